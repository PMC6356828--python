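"""End-to-end pipeline orchestration with provenance reporting.

A :class:`RunConfig` collects every input path and threshold; ``run_all``
executes assignment → differential expression → clustering → funnel → qPCR as
configured and writes a versioned JSON report embedding the full parameter set
and SHA-256 checksums of the inputs, so a report is auditable and a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .annotation_and_peaks import (
    assign_peaks, assignments_to_frame, read_annotation, read_peaks,
)
from .errors import HepatargetError, ValidationError
from .qpcr_quant import (
    DilutionSeries, OccupancySample, accept_primer, fit_standard_curve,
    occupancy_compare,
)
from .synthetic_data import read_confirmation
from .target_funnel import FunnelParams, TissuePanel, run_funnel
from .transcriptome_dynamics import (
    ExpressionMatrix, cluster_samples, diff_expression, induced_sets,
    transition_day,
)

REPORT_VERSION = 1

_REQUIRED_PATHS = ("genes", "peaks", "expression", "samples", "panel")


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    genes: str = ""
    peaks: str = ""
    expression: str = ""
    samples: str = ""
    panel: str = ""
    confirmation: Optional[str] = None
    dilutions: Optional[str] = None
    chip_ct: Optional[str] = None

    genes_format: str = "gtf"
    peaks_format: str = "narrowPeak"
    anchor: str = "summit"
    max_dist: int = 100_000
    dependency_fold: float = 4.0
    dependency_p: float = 0.05
    induced_fold: float = 4.0
    induced_p: float = 0.01
    window_bp: int = 1000
    min_liver_rank: int = 13
    induction_fold: float = 4.0
    endoderm_day: int = 5
    depletion_day: int = 8
    regulator: str = "HNF4A"
    target_tissue: str = "liver"
    efficiency_lo: float = 0.90
    efficiency_hi: float = 1.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    def validate(self) -> None:
        for name in _REQUIRED_PATHS:
            value = getattr(self, name)
            if not value:
                raise ValidationError(f"missing required config field: {name!r}")
            if not Path(value).exists():
                raise ValidationError(f"config field {name!r}: no such file {value!r}")
        for name in ("confirmation", "dilutions", "chip_ct"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ValidationError(f"config field {name!r}: no such file {value!r}")
        if not 0 <= self.efficiency_lo <= self.efficiency_hi:
            raise ValidationError("efficiency bounds must satisfy 0 <= lo <= hi")
        if self.window_bp < 0 or self.max_dist < 0:
            raise ValidationError("window_bp and max_dist must be nonnegative")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fit_curve_table(dilutions_path, lo: float, hi: float) -> pd.DataFrame:
    table = pd.read_csv(dilutions_path, sep="\t")
    rows = []
    for primer, group in table.groupby("primer", sort=True):
        group = group.sort_values("amount", ascending=False)
        series = DilutionSeries.from_amounts(group["amount"], group["ct"])
        curve = fit_standard_curve(series)
        rows.append({
            "primer": primer,
            "slope": curve.slope,
            "intercept": curve.intercept,
            "efficiency": curve.efficiency,
            "r2": curve.r2,
            "accepted": accept_primer(curve, lo, hi),
        })
    return pd.DataFrame(rows)


def _occupancy_table(chip_ct_path) -> pd.DataFrame:
    table = pd.read_csv(chip_ct_path, sep="\t")
    rows = []
    for target, group in table.groupby("target", sort=True):
        samples = {}
        for condition, sub in group.groupby("condition"):
            samples[condition] = [
                OccupancySample(target, condition, r.ct_ip, r.ct_input,
                                r.input_fraction)
                for r in sub.itertuples()
            ]
        if "control" not in samples or "depleted" not in samples:
            continue
        cmp = occupancy_compare(samples["depleted"], samples["control"])
        rows.append({
            "target": target,
            "mean_depleted": cmp.mean_a,
            "mean_control": cmp.mean_b,
            "difference": cmp.difference,
            "p_value": cmp.p_value,
            "n": cmp.n_b,
        })
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the configured pipeline and write all result tables plus report.json."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        genes = read_annotation(config.genes, format=config.genes_format)
        peaks = read_peaks(config.peaks, format=config.peaks_format)
        result = assign_peaks(peaks, genes, anchor=config.anchor,
                              max_abs_distance=config.max_dist)
    except HepatargetError as exc:
        raise ValidationError(f"assignment stage ({config.peaks}): {exc}") from exc
    assignment_frame = assignments_to_frame(result)
    assignment_frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    expr = ExpressionMatrix.read(config.expression, config.samples)
    control = expr.select(condition="control", day=config.depletion_day)
    depleted = expr.select(condition="depleted", day=config.depletion_day)
    if not control or not depleted:
        raise ValidationError(
            f"diff stage ({config.expression}): need control and depleted "
            f"samples at day {config.depletion_day}"
        )
    diff = diff_expression(expr, control, depleted)
    diff.to_csv(outdir / "diff.tsv", sep="\t", float_format="%.6g")

    tree = cluster_samples(expr, samples=expr.select(condition="control"))
    (outdir / "control_tree.nwk").write_text(tree.to_newick())
    pair = transition_day(tree, expr.meta)

    induced = induced_sets(expr, config.induced_fold, config.induced_p)
    with open(outdir / "induced_sets.tsv", "w") as fh:
        fh.write("day_from\tday_to\tgene\n")
        for (d1, d2), members in sorted(induced.items()):
            for gene in sorted(members):
                fh.write(f"{d1}\t{d2}\t{gene}\n")

    panel = TissuePanel.read(config.panel, config.target_tissue)
    confirmation = read_confirmation(config.confirmation) if config.confirmation else None
    params = FunnelParams(
        dependency_fold=config.dependency_fold,
        dependency_p=config.dependency_p,
        window_bp=config.window_bp,
        min_liver_rank=config.min_liver_rank,
        induction_fold=config.induction_fold,
        endoderm_day=config.endoderm_day,
        progenitor_day=config.depletion_day,
        regulator=config.regulator,
    )
    funnel = run_funnel(diff, assignment_frame, panel, expr, confirmation, params)
    (outdir / "funnel.json").write_text(funnel.to_json() + "\n")
    funnel.to_table().to_csv(outdir / "funnel_table.tsv", sep="\t", index=False)

    report = {
        "version": REPORT_VERSION,
        "parameters": asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("genes", "peaks", "expression", "samples", "panel",
                         "confirmation", "dilutions", "chip_ct")
            if getattr(config, name)
        },
        "n_peaks": len(peaks),
        "n_genes": len(genes),
        "n_assigned_peaks": int(assignment_frame["peak_name"].nunique()),
        "n_unassigned_peaks": len(result.unassigned),
        "transition_day_pair": list(pair) if pair else None,
        "induced_set_sizes": {f"{d1}->{d2}": len(m)
                              for (d1, d2), m in sorted(induced.items())},
        "funnel_counts": funnel.counts(),
        "final_targets": sorted(funnel.stage_sets["confirmed"]),
    }

    if config.dilutions:
        curves = _fit_curve_table(config.dilutions, config.efficiency_lo,
                                  config.efficiency_hi)
        curves.to_csv(outdir / "qpcr_curves.tsv", sep="\t", index=False,
                      float_format="%.6g")
        report["qpcr_primers_accepted"] = int(curves["accepted"].sum())
        report["qpcr_primers_total"] = int(len(curves))
    if config.chip_ct:
        occupancy = _occupancy_table(config.chip_ct)
        occupancy.to_csv(outdir / "occupancy.tsv", sep="\t", index=False,
                         float_format="%.6g")
        report["occupancy_targets_tested"] = int(len(occupancy))

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
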