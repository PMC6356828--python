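"""Synthetic study bundles with planted ground truth.

The generator emulates the design of a differentiation time-course study of
hepatic progenitor formation: a small genome annotation with strand-assigned
TSSs, regulator-bound peaks planted at known signed offsets from chosen TSSs
(plus Poisson background peaks), a daily expression time course in which a
hepatic program switches on across a programmed transition day pair, a matched
regulator-depleted condition in which that program fails to activate, a
16-tissue expression panel in which the planted targets are liver-enriched,
and qPCR dilution/Ct tables generated from a known efficiency model.

Every draw flows from a single seed; regenerating a bundle with the same
configuration is byte-identical.  A :class:`TruthManifest` records the planted
truths, and :func:`audit_bundle` re-derives each claim from the emitted files
using the analysis modules themselves.

Noise model: multiplicative log-normal on expression (sigma in log2 units),
additive Gaussian on Ct values — the same model assumed by the power
simulations in the analysis modules' property tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_and_peaks import (
    GeneModel, Peak, assign_peaks, read_annotation, read_peaks,
    write_annotation, write_peaks,
)
from .errors import ValidationError
from .target_funnel import TissuePanel, liver_enrichment, load_table1
from .transcriptome_dynamics import ExpressionMatrix, cluster_samples, diff_expression, transition_day

#: promoter-proximal offsets of the packaged 25-candidate table, reused as the
#: default planted site offsets (cycled when more targets are requested)
def _default_offsets() -> tuple:
    return tuple(r.site_offset for r in load_table1().values())


@dataclass
class ScenarioConfig:
    """Study-design parameters for one synthetic bundle.

    Defaults emulate the study conditions: 500 genes over 4 chromosomes, a
    daily course from day 3 to day 10 with the identity switch between days 7
    and 8, three replicate differentiations, a depleted condition sampled at
    days 6/8/10 whose hepatic program never activates, a 16-tissue panel, and
    planted induction folds spanning the printed candidate-table range.
    """

    n_genes: int = 500
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_planted_targets: int = 12
    planted_site_offsets: Optional[Tuple[int, ...]] = None
    transition_day_pair: Tuple[int, int] = (7, 8)
    days: Tuple[int, ...] = (3, 4, 5, 6, 7, 8, 10)
    depleted_days: Tuple[int, ...] = (6, 8, 10)
    replicates_per_day: int = 3
    depletion_effect: float = math.inf  # log2 reduction of the planted program
    n_tissues: int = 16
    target_tissue: str = "liver"
    liver_enrichment_factor: float = 8.0
    noise_sigma_log2: float = 0.25
    tissue_noise_sigma_log2: float = 0.5
    induction_fold_range: Tuple[float, float] = (4.74, 397.18)
    n_hepatic_extra: int = 38
    n_endoderm_genes: int = 50
    endoderm_shift_log2: float = 3.0
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 1.5
    background_peak_density: float = 2.5e-5  # peaks per bp, Poisson-placed
    qpcr_efficiency_range: Tuple[float, float] = (0.90, 1.10)
    ct_noise_sigma: float = 0.1
    input_fraction: float = 0.01
    occupancy_depletion_factor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.planted_site_offsets is None:
            self.planted_site_offsets = _default_offsets()
        for name in ("n_genes", "n_chroms", "chrom_length", "n_planted_targets",
                     "replicates_per_day", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_planted_targets > self.n_genes:
            raise ValidationError("cannot plant more targets than genes")
        if (self.n_planted_targets + self.n_hepatic_extra + self.n_endoderm_genes
                > self.n_genes):
            raise ValidationError("program sizes exceed the gene count")
        if list(self.days) != sorted(set(self.days)):
            raise ValidationError("days must be strictly increasing")
        d1, d2 = self.transition_day_pair
        days = list(self.days)
        if d1 not in days or d2 not in days or days.index(d2) != days.index(d1) + 1:
            raise ValidationError("transition_day_pair must be consecutive in days")
        genes_per_chrom = -(-self.n_genes // self.n_chroms)
        slot = self.chrom_length // genes_per_chrom
        max_off = max(abs(o) for o in self.planted_site_offsets)
        if slot < 2 * (max_off + 200):
            raise ValidationError(
                "planted offsets exceed chromosome bounds: genes too dense for "
                f"|offset| up to {max_off} bp"
            )


@dataclass
class TruthManifest:
    """Planted truths recorded alongside a bundle, for audit and recovery tests."""

    planted_target_ids: list
    site_offsets: dict          # gene_id -> signed bp
    induction_folds: dict       # gene_id -> linear fold (planted)
    liver_ranks: dict           # gene_id -> realized rank in the emitted panel
    transition_day_pair: tuple
    hepatic_program: list
    endoderm_program: list
    depleted_program: list
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        data = json.loads(text)
        data["transition_day_pair"] = tuple(data["transition_day_pair"])
        return cls(**data)


@dataclass
class Bundle:
    """Paths of one generated input bundle."""

    root: Path
    genes_gtf: Path
    peaks: Path
    expression: Path
    samples: Path
    panel: Path
    confirmation: Path
    dilutions: Path
    chip_ct: Path
    manifest: Path

    @classmethod
    def at(cls, root) -> "Bundle":
        root = Path(root)
        return cls(
            root=root,
            genes_gtf=root / "genes.gtf",
            peaks=root / "peaks.narrowPeak",
            expression=root / "expression.tsv",
            samples=root / "samples.tsv",
            panel=root / "tissue_panel.tsv",
            confirmation=root / "confirmation.tsv",
            dilutions=root / "qpcr_dilutions.tsv",
            chip_ct=root / "chip_ct.tsv",
            manifest=root / "manifest.json",
        )


# ---------------------------------------------------------------------------
# Generation


def _make_genes(config: ScenarioConfig, rng: np.random.Generator) -> list:
    genes_per_chrom = -(-config.n_genes // config.n_chroms)
    slot = config.chrom_length // genes_per_chrom
    jitter = max(0, slot // 2 - 2000)
    genes = []
    gi = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        on_chrom = min(genes_per_chrom, config.n_genes - gi)
        for k in range(on_chrom):
            tss0 = k * slot + slot // 2
            if jitter:
                tss0 += int(rng.integers(-jitter, jitter + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(1000, 3001))
            if strand == "+":
                length = min(length, config.chrom_length - tss0)
                span = (tss0, tss0 + length)
            else:
                length = min(length, tss0 + 1)
                span = (tss0 + 1 - length, tss0 + 1)
            gid = f"G{gi + 1:04d}"
            genes.append(GeneModel(gid, gid, chrom, strand, span[0], span[1]))
            gi += 1
    return genes


def _make_peaks(
    config: ScenarioConfig, rng: np.random.Generator,
    genes: Sequence[GeneModel], target_idx: Sequence[int],
) -> tuple:
    """Planted promoter-proximal peaks plus Poisson background peaks."""
    peaks = []
    site_offsets = {}
    for j, gi in enumerate(target_idx):
        gene = genes[gi]
        offset = int(config.planted_site_offsets[j % len(config.planted_site_offsets)])
        site_offsets[gene.gene_id] = offset
        summit = gene.tss0 + offset if gene.strand == "+" else gene.tss0 - offset
        start = max(0, summit - 150)
        end = min(config.chrom_length, summit + 151)
        peaks.append(Peak(gene.chrom, start, end, f"planted_{gene.gene_id}",
                          float(int(rng.integers(200, 1000))), summit))
    planted_tss = {}
    for gi in target_idx:
        planted_tss.setdefault(genes[gi].chrom, []).append(genes[gi].tss0)
    bg = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_bg = int(rng.poisson(config.background_peak_density * config.chrom_length))
        guarded = np.array(sorted(planted_tss.get(chrom, [])), dtype=float)
        for _ in range(n_bg):
            center = int(rng.integers(500, config.chrom_length - 500))
            # keep background away from planted TSSs so truth stays unambiguous
            if guarded.size and np.min(np.abs(guarded - center)) < 2000:
                continue
            half = int(rng.integers(100, 201))
            start, end = center - half, center + half
            summit = int(np.clip(center + rng.integers(-50, 51), start, end - 1))
            bg += 1
            peaks.append(Peak(chrom, start, end, f"bg_{bg:04d}",
                              float(int(rng.integers(50, 500))), summit))
    return peaks, site_offsets


def _make_expression(
    config: ScenarioConfig, rng: np.random.Generator,
    gene_ids: Sequence[str], hepatic: Sequence[int], endoderm: Sequence[int],
    log2_folds: np.ndarray,
) -> ExpressionMatrix:
    n = len(gene_ids)
    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
    post_day = config.transition_day_pair[1]

    hepatic_shift = np.zeros(n)
    hepatic_shift[list(hepatic)] = log2_folds
    endoderm_shift = np.zeros(n)
    endoderm_shift[list(endoderm)] = config.endoderm_shift_log2

    depleted_hepatic = np.maximum(0.0, hepatic_shift - config.depletion_effect)
    depleted_hepatic[hepatic_shift == 0] = 0.0

    columns, meta_rows, data = [], [], []
    for condition, days in (("control", config.days), ("depleted", config.depleted_days)):
        for day in days:
            post = day >= post_day
            if condition == "control":
                mu = baseline + (hepatic_shift if post else 0.0) \
                    + (0.0 if post else endoderm_shift)
            else:
                mu = baseline + (depleted_hepatic if post else 0.0) + endoderm_shift
            for rep in range(1, config.replicates_per_day + 1):
                name = f"{'ctrl' if condition == 'control' else 'depl'}_d{day}_r{rep}"
                noise = rng.normal(0.0, config.noise_sigma_log2, size=n)
                columns.append(name)
                data.append(2.0 ** (mu + noise))
                meta_rows.append({"sample": name, "condition": condition,
                                  "day": day, "replicate": rep})
    values = pd.DataFrame(np.column_stack(data), index=list(gene_ids), columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    meta["day"] = meta["day"].astype("Int64")
    return ExpressionMatrix(values, meta)


def _make_panel(
    config: ScenarioConfig, rng: np.random.Generator,
    gene_ids: Sequence[str], target_idx: Sequence[int],
) -> TissuePanel:
    tissues = [config.target_tissue] + [
        f"tissue{i:02d}" for i in range(1, config.n_tissues)
    ]
    n = len(gene_ids)
    base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
    log2 = base[:, None] + rng.normal(
        0.0, config.tissue_noise_sigma_log2, size=(n, config.n_tissues)
    )
    log2[list(target_idx), 0] += math.log2(config.liver_enrichment_factor)
    values = pd.DataFrame(2.0 ** log2, index=list(gene_ids), columns=tissues)
    return TissuePanel(values, config.target_tissue)


def _make_qpcr_tables(
    config: ScenarioConfig, rng: np.random.Generator, target_ids: Sequence[str]
) -> tuple:
    lo, hi = config.qpcr_efficiency_range
    dil_rows, ct_rows = [], []
    for gene in target_ids:
        eff = rng.uniform(lo, hi)
        slope = -1.0 / math.log10(1.0 + eff)
        intercept = rng.uniform(33.0, 38.0)
        for amount in (1e4, 1e3, 1e2, 1e1, 1e0):
            ct = slope * math.log10(amount) + intercept \
                + rng.normal(0.0, config.ct_noise_sigma)
            dil_rows.append({"primer": gene, "amount": amount, "ct": round(ct, 4)})
        # ChIP-qPCR occupancy: control enriched over depleted
        pi_control = 1.0
        pi_depleted = pi_control / config.occupancy_depletion_factor
        f = config.input_fraction
        for condition, pi in (("control", pi_control), ("depleted", pi_depleted)):
            for rep in range(1, config.replicates_per_day + 1):
                ct_input = rng.normal(20.0, 0.3)
                ct_ip = ct_input - math.log2(pi / (100.0 * f)) \
                    + rng.normal(0.0, config.ct_noise_sigma)
                ct_rows.append({
                    "target": gene, "condition": condition, "replicate": rep,
                    "ct_ip": round(ct_ip, 4), "ct_input": round(ct_input, 4),
                    "input_fraction": f,
                })
    return pd.DataFrame(dil_rows), pd.DataFrame(ct_rows)


def make_bundle(config: ScenarioConfig, outdir) -> tuple:
    """Generate a complete input bundle under ``outdir``.

    Returns ``(bundle, manifest)``; regenerating with the same configuration
    (seed included) reproduces every file byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    bundle = Bundle.at(outdir)
    bundle.root.mkdir(parents=True, exist_ok=True)

    genes = _make_genes(config, rng)
    gene_ids = [g.gene_id for g in genes]
    order = rng.permutation(config.n_genes)
    target_idx = sorted(int(i) for i in order[: config.n_planted_targets])
    hepatic_extra = sorted(
        int(i) for i in
        order[config.n_planted_targets: config.n_planted_targets + config.n_hepatic_extra]
    )
    endoderm_idx = sorted(
        int(i) for i in
        order[config.n_planted_targets + config.n_hepatic_extra:
              config.n_planted_targets + config.n_hepatic_extra + config.n_endoderm_genes]
    )
    hepatic_idx = sorted(target_idx + hepatic_extra)

    peaks, site_offsets = _make_peaks(config, rng, genes, target_idx)

    lo, hi = config.induction_fold_range
    log2_folds = rng.uniform(math.log2(lo), math.log2(hi), size=len(hepatic_idx))
    fold_by_gene = {gene_ids[gi]: float(2.0 ** f)
                    for gi, f in zip(hepatic_idx, log2_folds)}

    expr = _make_expression(config, rng, gene_ids, hepatic_idx, endoderm_idx, log2_folds)
    panel = _make_panel(config, rng, gene_ids, target_idx)

    target_ids = [gene_ids[i] for i in target_idx]
    dilutions, chip_ct = _make_qpcr_tables(config, rng, target_ids)

    confirmation = pd.DataFrame({
        "gene": target_ids,
        "occupancy": ["yes"] * len(target_ids),
        "qpcr_fc": [round(-fold_by_gene[g], 4) for g in target_ids],
    })

    write_annotation(genes, bundle.genes_gtf, format="gtf")
    write_peaks(peaks, bundle.peaks, format="narrowPeak")
    expr.write(bundle.expression, bundle.samples)
    panel.write(bundle.panel)
    confirmation.to_csv(bundle.confirmation, sep="\t", index=False)
    dilutions.to_csv(bundle.dilutions, sep="\t", index=False, float_format="%.6g")
    chip_ct.to_csv(bundle.chip_ct, sep="\t", index=False, float_format="%.6g")

    manifest = TruthManifest(
        planted_target_ids=target_ids,
        site_offsets=site_offsets,
        induction_folds={g: fold_by_gene[g] for g in target_ids},
        liver_ranks={g: liver_enrichment(panel, g)[1] for g in target_ids},
        transition_day_pair=tuple(config.transition_day_pair),
        hepatic_program=[gene_ids[i] for i in hepatic_idx],
        endoderm_program=[gene_ids[i] for i in endoderm_idx],
        depleted_program=[gene_ids[i] for i in hepatic_idx],
        seed=config.seed,
    )
    bundle.manifest.write_text(manifest.to_json() + "\n")
    return bundle, manifest


# ---------------------------------------------------------------------------
# Audit


@dataclass
class AuditReport:
    passed: bool
    failures: list = field(default_factory=list)


def audit_bundle(bundle: Bundle, manifest: Optional[TruthManifest] = None,
                 log2_tolerance: float = 1.0) -> AuditReport:
    """Re-derive every manifest claim from the emitted files.

    Site offsets are recomputed with peak-to-TSS assignment (exact match
    required), liver ranks with the panel enrichment rule (exact), planted
    induction folds with the depletion-free time course (within
    ``log2_tolerance`` log2 units, allowing for the emitted sampling noise),
    and the transition day pair with unsupervised clustering of the control
    samples.
    """
    if manifest is None:
        manifest = TruthManifest.from_json(bundle.manifest.read_text())
    failures = []

    genes = read_annotation(bundle.genes_gtf, format="gtf")
    peaks = read_peaks(bundle.peaks, format="narrowPeak")
    result = assign_peaks(peaks, genes, anchor="summit", max_abs_distance=100_000)
    observed = {}
    for a in result.assignments:
        observed.setdefault(a.gene.gene_id, set()).add(a.signed_distance)
    for gene, offset in manifest.site_offsets.items():
        if offset not in observed.get(gene, set()):
            failures.append(f"site offset mismatch for {gene}: "
                            f"expected {offset}, found {sorted(observed.get(gene, []))}")

    expr = ExpressionMatrix.read(bundle.expression, bundle.samples)
    d_pre, d_post = manifest.transition_day_pair
    pre = expr.select(condition="control", day=d_pre)
    post = expr.select(condition="control", day=d_post)
    table = diff_expression(expr, pre, post)
    for gene, fold in manifest.induction_folds.items():
        measured = float(table.at[gene, "fold_change"])
        if measured <= 0 or abs(math.log2(measured) - math.log2(fold)) > log2_tolerance:
            failures.append(f"induction fold mismatch for {gene}: "
                            f"planted {fold:.3g}, measured {measured:.3g}")

    panel = TissuePanel.read(bundle.panel)
    for gene, rank in manifest.liver_ranks.items():
        _, observed_rank = liver_enrichment(panel, gene)
        if observed_rank != rank:
            failures.append(f"liver rank mismatch for {gene}: "
                            f"manifest {rank}, panel {observed_rank}")

    control = expr.select(condition="control")
    tree = cluster_samples(expr, samples=control)
    pair = transition_day(tree, expr.meta)
    if pair != tuple(manifest.transition_day_pair):
        failures.append(f"transition day mismatch: manifest "
                        f"{tuple(manifest.transition_day_pair)}, clustering {pair}")

    return AuditReport(passed=not failures, failures=failures)


def read_confirmation(path) -> dict:
    """Read a confirmation TSV (gene, occupancy yes/no/N.D., qpcr_fc) to a mapping."""
    table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    out = {}
    for _, row in table.iterrows():
        fc = row.get("qpcr_fc")
        out[row["gene"]] = {
            "occupancy": str(row["occupancy"]),
            "qpcr_fc": None if pd.isna(fc) else float(fc),
        }
    return out
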