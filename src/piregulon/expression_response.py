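"""Target derepression statistics.

Counts are normalized by median-of-ratios size factors, fold changes
are computed on condition means with a pseudocount, target tiers are
compared by ECDF / two-sample Kolmogorov-Smirnov, and per-feature
differential tests (Welch t on log2 normalized counts) are corrected by
Benjamini-Hochberg. This is a transparent, fully specified stand-in for
a count-model DE engine: it answers "is the top-targeted tier shifted
toward up-regulation after effector loss?", not "what is the exact
per-gene posterior fold change".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Feature x sample counts with per-sample condition labels."""

    counts: pd.DataFrame  # features x samples, non-negative
    conditions: dict[str, str]  # sample id -> condition label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not out:
            raise ValueError(f"no samples with condition {condition!r}")
        return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: the median, over features with a nonzero geometric mean
    across samples, of count / geometric-mean.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no feature has nonzero counts in every sample")
    ratios = np.log(mat[usable]) - log_geo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Counts divided by median-of-ratios size factors."""
    sf = size_factors(matrix.counts)
    return matrix.counts / sf


def log2_fold_change(
    normalized: pd.DataFrame,
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature log2((mean_b + pc) / (mean_a + pc)): b relative to a."""
    a = normalized[matrix.samples_of(condition_a)].mean(axis=1)
    b = normalized[matrix.samples_of(condition_b)].mean(axis=1)
    return np.log2((b + pseudocount) / (a + pseudocount)).rename("log2fc")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, with the
    asymptotic p-value (effective n = |x||y| / (|x|+|y|))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def signed_ks(x: Sequence[float], y: Sequence[float]) -> float:
    """KS D with sign: positive when x is stochastically larger (shifted
    right) relative to y at the point of maximal ECDF separation."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    diff = fy - fx  # x shifted right => ECDF_x below ECDF_y => positive
    i = int(np.argmax(np.abs(diff)))
    return float(diff[i])


@dataclass
class GroupComparison:
    """ECDF vectors per tier plus all pairwise KS comparisons."""

    groups: dict[str, np.ndarray]
    pairwise: pd.DataFrame  # group_a, group_b, D, signed_D, p


def compare_target_tiers(
    log2fc: pd.Series,
    tiers: Mapping[str, Sequence[str]],
) -> GroupComparison:
    """Compare log2 fold-change distributions between target tiers.

    ``tiers`` maps tier label (e.g. top / lower / nontarget) to disjoint
    feature-id sets drawn from the ranking. Empty tiers are skipped with
    a warning. ``signed_D`` is positive when the first group of the pair
    is shifted toward up-regulation.
    """
    labels = list(tiers)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            common = set(tiers[a]) & set(tiers[b])
            if common:
                raise ValueError(f"tiers {a!r} and {b!r} overlap: {sorted(common)[:3]}")
    groups = {}
    for label in labels:
        ids = [f for f in tiers[label] if f in log2fc.index]
        vals = log2fc.loc[ids].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("tier %r is empty; its comparisons are skipped", label)
            continue
        groups[label] = np.sort(vals)
    rows = []
    keys = list(groups)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            d, p = ks_two_sample(groups[a], groups[b])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "D": d,
                    "signed_D": signed_ks(groups[a], groups[b]),
                    "p": p,
                }
            )
    return GroupComparison(
        groups=groups,
        pairwise=pd.DataFrame(rows, columns=["group_a", "group_b", "D", "signed_D", "p"]),
    )


def benjamini_hochberg(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up FDR control: adjusted p-values and the rejection mask.

    adj_p(i) = min over j >= i (in ascending-p order) of p(j) * m / j,
    capped at 1; reject where adj_p <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return adj, adj <= alpha


def feature_volcano_table(
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature log2FC, Welch-t p-value, and BH-adjusted p (b vs a).

    The test is a two-sided Welch t-test on log2(normalized count + 1)
    across replicates; features with zero variance in both groups get
    p = 1. With fewer than 2 replicates per condition only fold changes
    are reported.
    """
    normalized = normalize_counts(matrix)
    lfc = log2_fold_change(normalized, matrix, condition_a, condition_b, pseudocount)
    table = pd.DataFrame({"log2fc": lfc})
    sa = matrix.samples_of(condition_a)
    sb = matrix.samples_of(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        logger.warning(
            "fewer than 2 replicates per condition: fold changes only, no test"
        )
        table["p"] = np.nan
        table["adj_p"] = np.nan
        table["significant"] = False
        return table
    la = np.log2(normalized[sa].to_numpy(dtype=float) + 1.0)
    lb = np.log2(normalized[sb].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    adj, reject = benjamini_hochberg(p, alpha=alpha)
    table["p"] = p
    table["adj_p"] = adj
    table["significant"] = reject
    return table


def read_count_matrix(counts_path, conditions_path) -> CountMatrix:
    """Read a feature x sample TSV plus a sample->condition map TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0)
    conditions = cond.iloc[:, 0].to_dict()
    return CountMatrix(counts=counts, conditions=conditions)
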