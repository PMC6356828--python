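"""Gene annotations, ChIP peak calls, and strand-aware peak-to-TSS assignment.

Coordinate conventions
----------------------
BED and narrowPeak intervals are 0-based half-open, as in the file formats.
A gene's transcription start site (TSS) is reported as a 1-based genomic
coordinate: the first base of the gene body on the + strand, the last base on
the − strand.  Signed peak-to-TSS distances are in bp in the gene's own
orientation: negative means the peak anchor lies upstream (5') of the TSS,
positive downstream.  Promoter-proximal binding sites therefore carry small
negative offsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

_STRANDS = frozenset("+-")


@dataclass(frozen=True)
class GeneModel:
    """One gene: identity, body interval (0-based half-open) and strand-derived TSS."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    span_start: int
    span_end: int

    def __post_init__(self):
        if self.strand not in _STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.span_start < self.span_end:
            raise ValidationError(
                f"gene {self.gene_id}: empty or inverted interval "
                f"[{self.span_start}, {self.span_end})"
            )

    @property
    def tss(self) -> int:
        """1-based TSS coordinate: span_start+1 on '+', span_end on '-'."""
        return self.span_start + 1 if self.strand == "+" else self.span_end

    @property
    def tss0(self) -> int:
        """0-based TSS coordinate (internal arithmetic)."""
        return self.tss - 1


@dataclass(frozen=True)
class Peak:
    """One called binding interval, optionally with a summit point."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit: Optional[int] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"peak {self.name}: empty or inverted interval [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValidationError(f"peak {self.name}: negative score {self.score}")
        if self.summit is not None and not self.start <= self.summit < self.end:
            raise ValidationError(
                f"peak {self.name}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    def anchor_point(self, anchor: str = "summit") -> int:
        """0-based point used for distance computation.

        ``anchor='summit'`` uses the summit when present and falls back to the
        interval midpoint; ``anchor='midpoint'`` always uses the midpoint.
        """
        if anchor == "summit" and self.summit is not None:
            return self.summit
        if anchor not in ("summit", "midpoint"):
            raise ValidationError(f"unknown anchor {anchor!r}")
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakAssignment:
    """A peak joined to its nearest gene, with the signed bp offset from the TSS."""

    peak: Peak
    gene: GeneModel
    signed_distance: int
    anchor: str
    ambiguous: bool = False


@dataclass(frozen=True)
class AssignmentResult:
    assignments: tuple
    unassigned: tuple


@dataclass(frozen=True)
class DistanceHistogram:
    bin_edges: tuple
    counts: tuple

    def __post_init__(self):
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValidationError("counts must have one entry per bin")


# ---------------------------------------------------------------------------
# Readers / writers


def _split_line(line: str) -> list:
    return re.split(r"\s+", line.strip())


def read_annotation(path, format: str = "gtf") -> list:
    """Read gene models from a GTF (``gene`` features) or BED6/BED12 file.

    Duplicate gene ids are rejected; malformed lines raise :class:`ParseError`
    with the offending line number.
    """
    if format not in ("gtf", "bed"):
        raise ValidationError(f"unknown annotation format {format!r}")
    genes: list = []
    seen: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                if format == "gtf":
                    gene = _parse_gtf_line(line)
                    if gene is None:
                        continue
                else:
                    gene = _parse_bed_gene_line(line)
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, f"malformed {format} record: {exc}") from exc
            if gene.gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_line(line: str) -> Optional[GeneModel]:
    fields = line.split("\t")
    if len(fields) != 9:
        raise ValueError(f"expected 9 tab-separated fields, got {len(fields)}")
    chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
    if feature != "gene":
        return None
    attributes = dict(_GTF_ATTR.findall(attrs))
    if "gene_id" not in attributes:
        raise ValueError("gene record lacks gene_id attribute")
    return GeneModel(
        gene_id=attributes["gene_id"],
        symbol=attributes.get("gene_name", attributes["gene_id"]),
        chrom=chrom,
        strand=strand,
        span_start=int(start) - 1,  # GTF is 1-based closed
        span_end=int(end),
    )


def _parse_bed_gene_line(line: str) -> GeneModel:
    fields = _split_line(line)
    if len(fields) < 6:
        raise ValueError(f"BED gene records need >=6 columns, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    return GeneModel(
        gene_id=name,
        symbol=name,
        chrom=chrom,
        strand=strand,
        span_start=int(start),
        span_end=int(end),
    )


def write_annotation(genes: Iterable[GeneModel], path, format: str = "gtf") -> None:
    with open(path, "w") as fh:
        for g in genes:
            if format == "gtf":
                fh.write(
                    f"{g.chrom}\thepatarget\tgene\t{g.span_start + 1}\t{g.span_end}"
                    f"\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";\n'
                )
            elif format == "bed":
                fh.write(
                    f"{g.chrom}\t{g.span_start}\t{g.span_end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
            else:
                raise ValidationError(f"unknown annotation format {format!r}")


def read_peaks(path, format: str = "narrowPeak") -> list:
    """Read peaks from BED3+ or ENCODE narrowPeak (10-column) files.

    For narrowPeak the summit is ``start + offset`` when the 10th column is
    >= 0, otherwise absent.  BED peaks have no summit.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValidationError(f"unknown peak format {format!r}")
    peaks: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 else 0.0
                summit = None
                if format == "narrowPeak":
                    if len(fields) != 10:
                        raise ValueError(
                            f"narrowPeak needs 10 columns, got {len(fields)}"
                        )
                    offset = int(fields[9])
                    if offset >= 0:
                        summit = start + offset
                peaks.append(
                    Peak(chrom=chrom, start=start, end=end, name=name, score=score,
                         summit=summit)
                )
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, f"malformed {format} record: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path, format: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if format == "narrowPeak":
                offset = -1 if p.summit is None else p.summit - p.start
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t."
                    f"\t0\t-1\t-1\t{offset}\n"
                )
            elif format == "bed":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                raise ValidationError(f"unknown peak format {format!r}")


# ---------------------------------------------------------------------------
# Assignment


def signed_tss_distance(point0: int, gene: GeneModel) -> int:
    """Signed bp offset of a 0-based point from a gene's TSS (upstream negative)."""
    d = point0 - gene.tss0
    return d if gene.strand == "+" else -d


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    anchor: str = "summit",
    max_abs_distance: int = 100_000,
) -> AssignmentResult:
    """Assign each peak to the gene whose TSS is nearest its anchor point.

    Peaks whose nearest TSS is farther than ``max_abs_distance`` are returned
    in ``unassigned``.  When two or more TSSs are exactly equidistant, the peak
    is assigned to all of them with ``ambiguous=True``.
    """
    if not genes:
        raise ValidationError("cannot assign peaks against an empty gene set")
    if max_abs_distance < 0:
        raise ValidationError("max_abs_distance must be nonnegative")
    if anchor not in ("summit", "midpoint"):
        raise ValidationError(f"unknown anchor {anchor!r}")

    by_chrom: dict = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    sorted_pos: dict = {}
    for chrom, idx in by_chrom.items():
        pos = np.array([genes[i].tss0 for i in idx])
        order = np.argsort(pos, kind="stable")
        sorted_pos[chrom] = (pos[order], [idx[k] for k in order])

    assignments: list = []
    unassigned: list = []
    for peak in peaks:
        if peak.chrom not in sorted_pos:
            unassigned.append(peak)
            continue
        pos, idx = sorted_pos[peak.chrom]
        a = peak.anchor_point(anchor)
        j = int(np.searchsorted(pos, a))
        candidates = []
        if j < len(pos):
            candidates.append(j)
        if j > 0:
            candidates.append(j - 1)
        best = min(abs(int(pos[k]) - a) for k in candidates)
        if best > max_abs_distance:
            unassigned.append(peak)
            continue
        # all genes whose TSS attains the minimal distance (either side, shared TSSs)
        lo = int(np.searchsorted(pos, a - best, side="left"))
        hi = int(np.searchsorted(pos, a + best, side="right"))
        winners = [idx[k] for k in range(lo, hi) if abs(int(pos[k]) - a) == best]
        ambiguous = len(winners) > 1
        for gi in winners:
            gene = genes[gi]
            assignments.append(
                PeakAssignment(
                    peak=peak,
                    gene=gene,
                    signed_distance=signed_tss_distance(a, gene),
                    anchor=anchor,
                    ambiguous=ambiguous,
                )
            )
    return AssignmentResult(tuple(assignments), tuple(unassigned))


def unique_target_genes(assignments) -> set:
    """Deduplicated gene ids over a collection of assignments (or a frame)."""
    if isinstance(assignments, pd.DataFrame):
        return set(assignments["gene_id"])
    return {a.gene.gene_id for a in assignments}


def distance_histogram(assignments, bin_edges: Sequence[float]) -> DistanceHistogram:
    """Histogram of signed TSS distances over the given strictly increasing edges."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValidationError("bin_edges must be strictly increasing with >=2 entries")
    dists = [a.signed_distance for a in assignments]
    counts, _ = np.histogram(dists, bins=edges)
    return DistanceHistogram(tuple(float(e) for e in edges), tuple(int(c) for c in counts))


def assignments_to_frame(result) -> pd.DataFrame:
    """Tabulate assignments: peak name/coords, gene id, signed distance, flags."""
    assignments = result.assignments if isinstance(result, AssignmentResult) else result
    rows = [
        {
            "peak_name": a.peak.name,
            "chrom": a.peak.chrom,
            "peak_start": a.peak.start,
            "peak_end": a.peak.end,
            "gene_id": a.gene.gene_id,
            "signed_distance": a.signed_distance,
            "anchor": a.anchor,
            "ambiguous": a.ambiguous,
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peak_name", "chrom", "peak_start", "peak_end",
            "gene_id", "signed_distance", "anchor", "ambiguous",
        ],
    )
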