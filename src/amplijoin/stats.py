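"""Read filters, category frequencies, and replicate statistics.

Variant-sequence review pools follow the amplicon analysis convention: a
distinct read sequence is kept for individual review when it represents at
least 0.1% of its pool (deletion reads, or the combination of insertion and
complex-indel reads). Group comparisons use unpaired two-sample t-tests
(Student pooled-variance by default, Welch by flag) with Holm–Šidák step-down
correction within an explicitly declared family of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CATEGORIES, COMPLEX_INDEL, DELETION, INSERTION, UNCLASSIFIED

__all__ = [
    "variant_pool",
    "filter_variant_sequences",
    "category_frequencies",
    "unpaired_t",
    "holm_sidak",
    "fold_effect",
    "FoldEffect",
    "compare_groups",
]

FILTER_THRESHOLD = 0.001  # 0.1% of the pool


def variant_pool(calls: pd.DataFrame, pool: str) -> tuple[pd.Series, int]:
    """Distinct-sequence read counts for a review pool and the pool size.

    ``pool`` is ``"deletions"`` or ``"insertions_plus_complex"``; the pool
    size (the filter denominator) is the total number of reads in the pool.
    """
    if pool == "deletions":
        sub = calls[calls["category"] == DELETION]
    elif pool == "insertions_plus_complex":
        sub = calls[calls["category"].isin([INSERTION, COMPLEX_INDEL])]
    else:
        raise ValueError(f"unknown pool {pool!r}")
    counts = sub.groupby("sequence").size().sort_values(ascending=False)
    return counts, int(len(sub))


def filter_variant_sequences(
    variant_counts: pd.Series | dict,
    pool_total: int | None = None,
    threshold: float = FILTER_THRESHOLD,
) -> tuple[pd.Series, float]:
    """Retain variants representing at least ``threshold`` of the pool.

    Returns ``(retained_counts, removed_mass)`` where ``removed_mass`` is the
    fraction of pool reads dropped. A variant at exactly the threshold is
    retained. An empty pool returns an empty series (with a warning) and
    removed mass 0.
    """
    counts = pd.Series(variant_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("variant counts must be non-negative")
    total = float(counts.sum()) if pool_total is None else float(pool_total)
    if total <= 0:
        warnings.warn("filter_variant_sequences: empty pool", stacklevel=2)
        return counts.iloc[0:0], 0.0
    share = counts / total
    retained = counts[share >= threshold - 1e-12]
    removed_mass = float((counts.sum() - retained.sum()) / total)
    return retained, removed_mass


def category_frequencies(calls: pd.DataFrame, sample: str = "") -> pd.Series:
    """Category frequencies over classified (non-Unclassified) reads.

    Frequencies sum to 1 over the four repair-outcome categories. Read
    accounting (classified / unclassified / total) is attached in ``attrs``.
    Raises if no read classified.
    """
    total = len(calls)
    classified = calls[calls["category"] != UNCLASSIFIED]
    if len(classified) == 0:
        raise ValueError(f"no classified reads{f' in sample {sample}' if sample else ''}")
    freqs = (
        classified["category"].value_counts().reindex(list(CATEGORIES), fill_value=0)
        / len(classified)
    )
    freqs.attrs["n_total"] = total
    freqs.attrs["n_classified"] = int(len(classified))
    freqs.attrs["n_unclassified"] = total - int(len(classified))
    return freqs


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float], welch: bool = False) -> float:
    """Two-sided p of the unpaired two-sample t-test.

    Student pooled-variance by default; Welch with ``welch=True``. Degenerate
    zero-variance groups: equal means give p = 1, unequal means p = 0 (with a
    warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups contain non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0", stacklevel=2)
        return 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest (1-based) becomes
    ``1 - (1 - p_(i))**(m - i + 1)``; a running maximum enforces monotonicity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class FoldEffect:
    """x-fold change between two group means, with direction a -> b."""

    ratio: float  # >= 1
    direction: str  # 'increase' | 'decrease' | 'none'

    def __str__(self) -> str:
        if self.direction == "none":
            return "1.0-fold"
        return f"{self.ratio:.1f}-fold {self.direction}"


def fold_effect(mean_a: float, mean_b: float) -> FoldEffect:
    """Fold change from condition a to condition b (ratio of means, >= 1)."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("fold effect undefined for non-positive means")
    if mean_a == mean_b:
        return FoldEffect(1.0, "none")
    if mean_b > mean_a:
        return FoldEffect(mean_b / mean_a, "increase")
    return FoldEffect(mean_a / mean_b, "decrease")


def compare_groups(
    data: pd.DataFrame,
    value: str,
    group: str,
    comparisons: Iterable[tuple[str, str]],
    welch: bool = False,
) -> pd.DataFrame:
    """Family of unpaired t-tests with Holm–Šidák correction.

    ``comparisons`` lists ``(group_a, group_b)`` labels forming one
    multiple-testing family (one figure-style panel). Returns a tidy frame
    with group means +/- SD, n, raw and adjusted p, and the fold effect.
    """
    comparisons = list(comparisons)
    rows = []
    for ga, gb in comparisons:
        a = data.loc[data[group] == ga, value].to_numpy(dtype=float)
        b = data.loc[data[group] == gb, value].to_numpy(dtype=float)
        fe = fold_effect(a.mean(), b.mean()) if a.mean() > 0 and b.mean() > 0 else None
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "n_a": a.size,
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "n_b": b.size,
                "p_raw": unpaired_t(a, b, welch=welch),
                "fold": fe.ratio if fe else np.nan,
                "direction": fe.direction if fe else "undefined",
                "test": "welch" if welch else "student",
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())
    return out
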