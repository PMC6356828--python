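"""Time-course expression analysis: fold changes, induced gene sets, clustering.

Expression values are linear-scale, nonnegative array intensities.  A
configurable pseudo-signal floor (default 1.0) is added before any log2
transform or ratio to stabilize genes near zero.  Fold changes follow the
signed-ratio convention: +r means group B is r-fold above group A, −r means
r-fold below; the magnitude is always >= 1.

Sample clustering uses 1 − Pearson correlation of log2 profiles with average
linkage by default, the standard treatment for array expression profiles.
Ties in merge height are resolved by scipy's deterministic input-order rule,
so a fixed sample order yields a fixed tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

REQUIRED_META = ("condition", "day", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes × samples linear intensities plus per-sample metadata.

    ``meta`` is indexed by sample name with columns ``condition`` (e.g.
    control / depleted / tissue-panel), ``day`` (nullable integer) and
    ``replicate``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns: {missing}")
        if set(self.values.columns) != set(self.meta.index):
            raise ValidationError("sample metadata does not cover the value columns")
        self.meta = self.meta.loc[self.values.columns]

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def select(self, condition: Optional[str] = None, day: Optional[int] = None) -> list:
        """Sample names matching the given condition and/or day."""
        mask = pd.Series(True, index=self.meta.index)
        if condition is not None:
            mask &= self.meta["condition"] == condition
        if day is not None:
            mask &= self.meta["day"] == day
        return list(self.meta.index[mask])

    @classmethod
    def read(cls, values_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0).astype(float)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "day" in meta.columns:
            meta["day"] = meta["day"].astype("Int64")
        return cls(values, meta)

    def write(self, values_path, meta_path, float_format: str = "%.6g") -> None:
        self.values.to_csv(values_path, sep="\t", float_format=float_format)
        self.meta.to_csv(meta_path, sep="\t")


@dataclass
class ClusterTree:
    """Binary merge tree over samples (scipy linkage matrix + leaf names)."""

    linkage: np.ndarray
    samples: Tuple[str, ...]

    def flat_labels(self, k: int) -> dict:
        """Partition into (at most) k groups; returns sample -> integer label."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(x) for x in labels)))

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.samples))
        return str(tree)


def _log2_floor(values: pd.DataFrame, floor: float) -> pd.DataFrame:
    return np.log2(values + floor)


def diff_expression(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene signed fold change and Welch p-value between two sample groups.

    Fold change is the ratio of floored linear group means, signed so that
    negative means group B is reduced relative to group A.  The p-value is a
    two-sided unequal-variance t-test on log2(value + floor); it is NaN when
    either group has fewer than two samples.  Genes with zero mean in both
    groups (before flooring) have an undefined fold change and are flagged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must contain at least one sample")
    A = expr.values[group_a].to_numpy(dtype=float)
    B = expr.values[group_b].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    undefined = (mean_a == 0) & (mean_b == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (mean_b + floor) / (mean_a + floor)
        fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
    fc = np.where(undefined, np.nan, fc)

    if len(group_a) >= 2 and len(group_b) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(
                np.log2(A + floor), np.log2(B + floor), axis=1, equal_var=False
            )
    else:
        p = np.full(len(mean_a), np.nan)

    return pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "undefined": undefined,
        },
        index=expr.values.index,
    )


def induced_sets(
    expr: ExpressionMatrix,
    fold_threshold: float = 4.0,
    p_threshold: float = 0.01,
    condition: str = "control",
    floor: float = 1.0,
) -> dict:
    """Genes changing >= fold_threshold between consecutive days (robust induction).

    Returns ``{(day_i, day_j): set_of_gene_ids}`` over consecutive pairs of the
    distinct days present for the condition.  Membership requires
    |fold change| >= fold_threshold in either direction AND p <= p_threshold;
    if a day has a single replicate the p criterion is unavailable and the
    fold criterion alone decides.
    """
    days = sorted(
        int(d) for d in expr.meta.loc[expr.meta["condition"] == condition, "day"]
        .dropna().unique()
    )
    result: dict = {}
    if len(days) < 2:
        return result
    for d1, d2 in zip(days, days[1:]):
        g1 = expr.select(condition=condition, day=d1)
        g2 = expr.select(condition=condition, day=d2)
        table = diff_expression(expr, g1, g2, floor=floor)
        passes = table["fold_change"].abs() >= fold_threshold
        if len(g1) >= 2 and len(g2) >= 2:
            passes &= table["p_value"] <= p_threshold
        result[(d1, d2)] = set(table.index[passes.fillna(False)])
    return result


def cluster_samples(
    expr: ExpressionMatrix,
    distance: str = "one-minus-pearson",
    linkage: str = "average",
    floor: float = 1.0,
    samples: Optional[Sequence[str]] = None,
) -> ClusterTree:
    """Hierarchical clustering of sample expression profiles.

    ``distance='one-minus-pearson'`` computes 1 − Pearson correlation of log2
    profiles; ``'euclidean-log2'`` uses Euclidean distance on log2 values.
    """
    cols = list(samples) if samples is not None else expr.samples
    if len(cols) < 2:
        raise ValidationError("clustering needs at least two samples")
    log2 = _log2_floor(expr.values[cols], floor)
    X = log2.to_numpy(dtype=float).T  # samples × genes
    if distance == "one-minus-pearson":
        sds = X.std(axis=1)
        flat = [cols[i] for i in np.flatnonzero(sds == 0)]
        if flat:
            raise ValidationError(
                f"constant-variance sample(s) under correlation distance: {flat}"
            )
        d = pdist(X, metric="correlation")
    elif distance == "euclidean-log2":
        d = pdist(X, metric="euclidean")
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(d, method=linkage)
    return ClusterTree(Z, tuple(cols))


def transition_day(tree: ClusterTree, meta: pd.DataFrame, condition: str = "control"):
    """Boundary day pair implied by the k=2 cut, or None if no clean transition.

    Considers only samples of the given condition that carry a day label.  The
    cut is clean when it splits those samples into two non-empty groups whose
    day ranges do not interleave and no single day straddles the cut; the
    return value is then ``(last pre-transition day, first post-transition day)``.
    """
    labels = tree.flat_labels(2)
    day_by_label: dict = {}
    day_labels: dict = {}
    for sample, label in labels.items():
        if sample not in meta.index:
            continue
        row = meta.loc[sample]
        if row["condition"] != condition or pd.isna(row["day"]):
            continue
        day = int(row["day"])
        day_by_label.setdefault(label, set()).add(day)
        day_labels.setdefault(day, set()).add(label)
    if len(day_by_label) != 2:
        return None
    if any(len(ls) != 1 for ls in day_labels.values()):
        return None  # a day's replicates straddle the cut
    (la, days_a), (lb, days_b) = day_by_label.items()
    lo, hi = (days_a, days_b) if min(days_a) < min(days_b) else (days_b, days_a)
    if max(lo) >= min(hi):
        return None  # interleaved day ranges
    return (max(lo), min(hi))


def marker_heatmap_table(
    expr: ExpressionMatrix, marker_ids: Sequence[str], floor: float = 1.0
) -> pd.DataFrame:
    """log2 signal of the given marker genes, sample order preserved."""
    missing = [m for m in marker_ids if m not in expr.values.index]
    if missing:
        raise ValidationError(f"unknown marker id(s): {missing}")
    return _log2_floor(expr.values.loc[list(marker_ids)], floor)
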