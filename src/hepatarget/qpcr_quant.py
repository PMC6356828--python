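"""Standard-curve qPCR quantification and ChIP-qPCR occupancy statistics.

A serial dilution of template of known amount yields a standard curve
Ct = slope · log10(amount) + intercept.  The per-cycle amplification
efficiency is E = 10^(−1/slope) − 1; a perfect doubling assay has
slope −3.3219 and E = 100%.  Primer pairs are accepted when E falls in the
inclusive 90–110% band.

ChIP-qPCR enrichment is expressed as percent input with dilution correction:
an input aliquot representing fraction f of the chromatin is adjusted to
100% input, giving  %input = 100 · f · 2^(Ct_input − Ct_IP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # −3.3219...: doubling each cycle


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution points: (log10 template amount, Ct), amounts decreasing."""

    points: tuple  # ((log10_amount, ct), ...)

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValidationError("a dilution series needs at least 3 points")
        log_amounts = [p[0] for p in self.points]
        if any(b >= a for a, b in zip(log_amounts, log_amounts[1:])):
            raise ValidationError("template amounts must be strictly decreasing")
        if any(not math.isfinite(p[1]) for p in self.points):
            raise ValidationError("Ct values must be finite")

    @classmethod
    def from_amounts(cls, amounts: Sequence[float], cts: Sequence[float]) -> "DilutionSeries":
        if len(amounts) != len(cts):
            raise ValidationError("amounts and Cts must have equal length")
        if any(a <= 0 for a in amounts):
            raise ValidationError("template amounts must be positive")
        return cls(tuple((math.log10(a), float(c)) for a, c in zip(amounts, cts)))


class QpcrCurve(NamedTuple):
    slope: float
    intercept: float
    efficiency: float
    r2: float

    @property
    def amplifying(self) -> bool:
        return self.slope < 0


def fit_standard_curve(series: DilutionSeries) -> QpcrCurve:
    """Least-squares line Ct = slope·log10(amount) + intercept, with E and r²."""
    x = np.array([p[0] for p in series.points])
    y = np.array([p[1] for p in series.points])
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    efficiency = math.nan if slope == 0 else 10.0 ** (-1.0 / slope) - 1.0
    return QpcrCurve(slope, intercept, efficiency, float(fit.rvalue) ** 2)


def accept_primer(curve: QpcrCurve, lo: float = 0.90, hi: float = 1.10) -> bool:
    """Inclusive efficiency acceptance band (default 90–110%); requires a negative slope."""
    return curve.amplifying and lo <= curve.efficiency <= hi


def absolute_copies(ct: float, curve: QpcrCurve) -> float:
    """Template amount implied by a Ct on the standard curve: 10^((ct−b)/m)."""
    if curve.slope == 0:
        raise ValidationError("standard curve has zero slope; cannot invert")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class OccupancySample:
    """One ChIP-qPCR measurement of a locus in one condition."""

    target: str
    condition: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 1.0

    def __post_init__(self):
        if not 0 < self.input_fraction <= 1:
            raise ValidationError("input_fraction must lie in (0, 1]")


def percent_input(sample: OccupancySample) -> float:
    """Dilution-corrected percent input: 100 · f · 2^(Ct_input − Ct_IP)."""
    ct_input_adj = sample.ct_input + math.log2(sample.input_fraction)
    return 100.0 * 2.0 ** (ct_input_adj - sample.ct_ip)


class OccupancyComparison(NamedTuple):
    mean_a: float
    mean_b: float
    difference: float       # mean_b − mean_a, in percent-input units
    p_value: Optional[float]
    n_a: int
    n_b: int
    sem_a: float
    sem_b: float


def occupancy_compare(
    group_a: Sequence[OccupancySample],
    group_b: Sequence[OccupancySample],
    equal_var: bool = False,
) -> OccupancyComparison:
    """Difference of mean percent input between two sample groups with a
    two-sided t-test (Welch by default).

    With fewer than two replicates in either group the p-value is None.
    Degenerate zero-variance groups return p = 1 for a zero difference and
    p = 0 otherwise.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must contain at least one sample")
    a = np.array([percent_input(s) for s in group_a])
    b = np.array([percent_input(s) for s in group_b])
    diff = float(b.mean() - a.mean())
    sem_a = float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else math.nan
    sem_b = float(b.std(ddof=1) / math.sqrt(len(b))) if len(b) > 1 else math.nan
    if len(a) < 2 or len(b) < 2:
        p = None
    elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return OccupancyComparison(
        float(a.mean()), float(b.mean()), diff, p, len(a), len(b), sem_a, sem_b
    )


def collapse_technical_replicates(cts: Sequence[float]) -> float:
    """Arithmetic mean of technical-replicate Cts, taken before quantification."""
    if not len(cts):
        raise ValidationError("no Ct values to average")
    return float(np.mean(cts))
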