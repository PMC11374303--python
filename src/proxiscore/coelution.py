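"""SEC-MS co-elution analysis.

Size-exclusion chromatography fractions analyzed by quantitative MS give
each protein an elution profile over ordered fractions (earliest =
largest assemblies).  Proteins that genuinely share a complex with the
bait co-elute, so their profiles correlate with the bait's.  This module
normalizes profiles to their fraction sums, computes per-protein Pearson
correlations with the bait, compares correlation distributions between an
enriched set and the rest (Wilcoxon rank-sum with continuity correction),
and quantifies what fraction of a protein's signal falls inside
assembly-state peak windows.

Missing fraction values are pairwise-deleted for correlations (an
explicit zero-fill flag is available); they count as zero for fraction
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmax

__all__ = [
    "CoelutionResult",
    "normalize_profiles",
    "bait_correlations",
    "wilcoxon_rank_sum",
    "compare_enriched_correlations",
    "window_signal_fraction",
    "propose_windows",
]


@dataclass
class CoelutionResult:
    """Per-protein Pearson r with the bait and overlap bookkeeping."""

    table: pd.DataFrame  # columns: r, n_overlap
    bait_id: str
    meta: dict = field(default_factory=dict)


def normalize_profiles(run: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each profile by its fraction sum (missing counts as 0).

    Proteins whose total signal is zero are excluded and returned as the
    second element.  Missing entries stay missing in the output; rows
    sum to 1 when missing values are treated as zero.
    """
    values = run.to_numpy(dtype=float)
    totals = np.nansum(np.where(np.isnan(values), 0.0, values), axis=1)
    excluded = list(run.index[totals == 0])
    keep = totals > 0
    normalized = values[keep] / totals[keep, None]
    return pd.DataFrame(normalized, index=run.index[keep], columns=run.columns), excluded


def bait_correlations(run: pd.DataFrame, bait_id: str,
                      min_fractions: int = 5,
                      zero_fill: bool = False) -> CoelutionResult:
    """Pearson r of every protein's profile against the bait's.

    Correlations use fractions where both profiles are nonmissing
    (``zero_fill=True`` instead replaces missing with 0 first).  Proteins
    with fewer than ``min_fractions`` overlapping fractions, or with a
    constant profile over the overlap, get no r.
    """
    if bait_id not in run.index:
        raise ValueError(f"bait {bait_id!r} not present in the SEC run")
    values = run.to_numpy(dtype=float)
    if zero_fill:
        values = np.where(np.isnan(values), 0.0, values)
    bait = values[run.index.get_loc(bait_id)]
    if np.nanstd(bait) == 0:
        raise ValueError(f"bait {bait_id!r} profile is constant")

    r = np.full(values.shape[0], np.nan)
    n_overlap = np.zeros(values.shape[0], dtype=int)
    for i in range(values.shape[0]):
        both = ~np.isnan(values[i]) & ~np.isnan(bait)
        n_overlap[i] = both.sum()
        if n_overlap[i] < min_fractions:
            continue
        x, y = values[i, both], bait[both]
        if x.std() == 0 or y.std() == 0:
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
    tab = pd.DataFrame({"r": r, "n_overlap": n_overlap}, index=run.index)
    return CoelutionResult(tab, bait_id=bait_id,
                           meta={"min_fractions": min_fractions,
                                 "zero_fill": zero_fill})


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all label assignments (no ties)."""
    pooled = np.sort(np.concatenate([x, y]))
    n, m = x.size, y.size
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    center = n * m / 2
    dev = abs(u_obs - center)
    total = comb(n + m, n)
    hits = 0
    for ix in combinations(range(n + m), n):
        u = sum(ix) + n - n * (n + 1) / 2  # ranks are positions+1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Returns (U statistic of the first sample, two-sided p).  Ties get
    midranks and a tie-corrected normal variance; the normal approximation
    applies a 0.5 continuity correction.  For tie-free samples with
    combined size <= 12 the p-value is computed by exact enumeration of
    all label assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2

    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= 12 and not has_ties:
        return float(u), float(_exact_rank_sum_p(x, y))

    mu = n * m / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n + m) * (n + m - 1))
    var = n * m / 12 * (n + m + 1 - tie_term)
    if var == 0:
        return float(u), 1.0
    dev = abs(u - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    p = 2.0 * stats.norm.sf(dev / np.sqrt(var))
    return float(u), float(min(p, 1.0))


def compare_enriched_correlations(coelution: CoelutionResult,
                                  enriched_set) -> dict:
    """Do enriched proteins co-elute with the bait more than the rest?

    Wilcoxon rank-sum of the Pearson r values of the enriched set against
    all other proteins with a defined r (the bait itself is excluded).
    """
    tab = coelution.table.drop(index=coelution.bait_id, errors="ignore")
    defined = tab["r"].dropna()
    enriched_set = set(enriched_set)
    in_set = defined.index.isin(enriched_set)
    r_enriched = defined[in_set].to_numpy()
    r_rest = defined[~in_set].to_numpy()
    if r_enriched.size < 3 or r_rest.size < 3:
        raise ValueError(
            f"need >= 3 proteins with defined r per group, got "
            f"{r_enriched.size} enriched / {r_rest.size} rest")
    u, p = wilcoxon_rank_sum(r_enriched, r_rest)
    return {
        "n_enriched": int(r_enriched.size),
        "n_rest": int(r_rest.size),
        "median_r_enriched": float(np.median(r_enriched)),
        "median_r_rest": float(np.median(r_rest)),
        "statistic": u,
        "p_value": p,
    }


def window_signal_fraction(normalized: pd.DataFrame, protein_id: str,
                           windows: list[tuple[int, int]]) -> float:
    """Signal fraction inside the union of fraction windows (inclusive).

    Overlapping windows are unioned, never double-counted; missing values
    contribute zero.  Expects a sum-normalized run.
    """
    if protein_id not in normalized.index:
        raise ValueError(f"protein {protein_id!r} not present")
    keep: set = set()
    for start, stop in windows:
        keep.update(range(int(start), int(stop) + 1))
    cols = [c for c in normalized.columns if int(c) in keep]
    vals = normalized.loc[protein_id, cols].to_numpy(dtype=float)
    return float(np.nansum(vals))


def propose_windows(normalized: pd.DataFrame, anchor_ids,
                    half_width: int = 2) -> list[tuple[int, int]]:
    """Heuristic assembly-window proposal from the mean anchor profile.

    Takes local maxima of the mean profile of the anchor-positive
    proteins and returns +/- ``half_width`` fraction windows around them.
    Real assignments of assembly states to peaks are a manual judgement;
    treat this strictly as a starting point.
    """
    ids = [i for i in anchor_ids if i in normalized.index]
    if not ids:
        raise ValueError("no anchor ids present in the normalized run")
    mean_profile = normalized.loc[ids].mean(axis=0, skipna=True).to_numpy()
    peaks = argrelmax(mean_profile, order=1)[0]
    fractions = [int(normalized.columns[i]) for i in peaks]
    lo, hi = int(normalized.columns[0]), int(normalized.columns[-1])
    return [(max(lo, f - half_width), min(hi, f + half_width)) for f in fractions]
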