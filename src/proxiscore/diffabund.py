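"""Per-protein bait-vs-control differential abundance.

Implements the contrast used to score pull-down enrichment: global median
normalization of log2 intensities, a paired two-sided t-test on log2
bait/control ratios over complete replicate pairs, and q-value
multiple-testing correction with an estimated proportion of true nulls
(pi0).

Conventions (the underlying protein reports do not pin these down, so the
module documents its own):

* zero intensities are treated as missing before the log transform;
* a protein needs >= 2 complete bait/control pairs to receive a p-value;
* zero-variance differences: all d_i = 0 gives p = 1, all d_i equal and
  nonzero gives p = 0, both flagged as degenerate;
* ratios are log base 2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "median_normalize",
    "paired_log2_contrast",
    "storey_qvalues",
    "run_differential",
]


@dataclass
class ContrastResult:
    """Per-protein contrast: mean log2 ratio, p-value, q-value, n pairs.

    ``table`` is indexed by protein id with columns ``mean_log2_ratio``,
    ``p_value``, ``q_value``, ``n_pairs`` and ``degenerate``; ``meta``
    records the options and estimates (pi0, q clamp) of the run.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _as_log2(values: np.ndarray) -> np.ndarray:
    """Linear intensities to log2; nonpositive entries become missing."""
    out = np.where(values > 0, values, np.nan)
    return np.log2(out, where=~np.isnan(out), out=np.full_like(out, np.nan))


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Global median normalization on the log2 scale.

    Each sample's nonmissing log2 intensities are shifted so that every
    sample median equals the median of the pre-normalization sample
    medians; the result is returned on the linear scale with missing
    entries untouched.  Idempotent.
    """
    if table.shape[1] < 1:
        raise ValueError("table has no samples")
    log2 = _as_log2(table.to_numpy(dtype=float))
    n_obs = (~np.isnan(log2)).sum(axis=0)
    empty = np.flatnonzero(n_obs == 0)
    if empty.size:
        names = ", ".join(str(table.columns[i]) for i in empty)
        raise ValueError(f"sample(s) with no nonmissing values: {names}")
    medians = np.nanmedian(log2, axis=0)
    target = np.median(medians)
    shifted = log2 - medians[None, :] + target
    return pd.DataFrame(2.0 ** shifted, index=table.index, columns=table.columns)


def _pairs_for_condition(design: pd.DataFrame, condition: str) -> list[tuple[str, str]]:
    sub = design[design["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not found in design")
    pairs = []
    for pair_id, grp in sub.groupby("pair_id"):
        arms = dict(zip(grp["arm"], grp.index))
        if set(arms) != {"bait", "control"}:
            raise ValueError(
                f"pair {pair_id!r} does not have exactly one bait and one "
                f"control sample")
        pairs.append((arms["bait"], arms["control"]))
    if not pairs:
        raise ValueError(f"no bait/control pairs for condition {condition!r}")
    return pairs


def paired_log2_contrast(table: pd.DataFrame, design: pd.DataFrame,
                         condition: str) -> ContrastResult:
    """Paired two-sided t-test on per-pair log2 bait/control ratios.

    For each protein, d_i = log2(bait_i) - log2(control_i) over replicate
    pairs where both values are present; mean_log2_ratio is the mean of
    the d_i and the t statistic has n_pairs - 1 degrees of freedom.
    Proteins with fewer than two complete pairs carry no p-value.
    """
    missing = set(design.index) - set(table.columns)
    if missing:
        raise ValueError(f"design samples absent from table: {sorted(missing)}")
    pairs = _pairs_for_condition(design, condition)
    log2 = _as_log2(table.to_numpy(dtype=float))
    col_ix = {c: i for i, c in enumerate(table.columns)}
    d = np.stack([log2[:, col_ix[b]] - log2[:, col_ix[c]] for b, c in pairs],
                 axis=1)

    n_pairs = (~np.isnan(d)).sum(axis=1)
    mean = np.nansum(d, axis=1) / np.maximum(n_pairs, 1)
    mean[n_pairs == 0] = np.nan
    resid_ss = np.nansum((d - mean[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(resid_ss / np.maximum(n_pairs - 1, 1))
    sd[n_pairs < 2] = np.nan

    p = np.full(d.shape[0], np.nan)
    degenerate = np.zeros(d.shape[0], dtype=bool)
    testable = n_pairs >= 2
    zero_var = testable & (sd == 0)
    # zero-variance conventions: identical zero differences are a perfect
    # null, identical nonzero differences a perfect effect
    p[zero_var & (mean == 0)] = 1.0
    p[zero_var & (mean != 0)] = 0.0
    degenerate[zero_var] = True
    reg = testable & (sd > 0)
    if reg.any():
        t = mean[reg] / (sd[reg] / np.sqrt(n_pairs[reg]))
        p[reg] = 2.0 * stats.t.sf(np.abs(t), df=n_pairs[reg] - 1)

    out = pd.DataFrame({
        "mean_log2_ratio": mean,
        "p_value": p,
        "q_value": np.nan,
        "n_pairs": n_pairs,
        "degenerate": degenerate,
    }, index=table.index)
    return ContrastResult(out, meta={"condition": condition,
                                     "n_pairs_design": len(pairs)})


def storey_qvalues(p_values, lam: float | str = 0.5,
                   pi0_override: float | None = None) -> np.ndarray:
    """q-values with pi0 estimated from the upper tail of the p-values.

    pi0 is estimated as #{p > lambda} / (m * (1 - lambda)), clamped to
    [1/m, 1]; the q-value of the i-th ordered p is the minimum over j >= i
    of pi0 * m * p_(j) / j.  With ``pi0_override=1`` this reduces exactly
    to the Benjamini-Hochberg step-up adjustment.  ``lam='auto'`` runs a
    grid of lambda values (0.05..0.90 step 0.05) and takes a cubic
    polynomial smoother evaluated at the top of the grid.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and nonmissing")
    m = p.size

    if pi0_override is not None:
        pi0 = float(pi0_override)
        if not (0 < pi0 <= 1):
            raise ValueError(f"pi0_override must be in (0, 1], got {pi0}")
    elif lam == "auto":
        grid = np.arange(0.05, 0.9001, 0.05)
        pi0_grid = np.array([(p > g).sum() / (m * (1 - g)) for g in grid])
        coef = np.polyfit(grid, pi0_grid, deg=3)
        pi0 = float(np.polyval(coef, grid[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        lam = float(lam)
        if not (0 <= lam < 1):
            raise ValueError(f"lambda must be in [0, 1), got {lam}")
        pi0 = (p > lam).sum() / (m * (1 - lam))
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_differential(table: pd.DataFrame, design: pd.DataFrame, condition: str,
                     normalize: bool = True, impute: str = "none",
                     lam: float | str = 0.5,
                     pi0_override: float | None = None) -> ContrastResult:
    """Normalization + paired contrast + q-values, in one call.

    ``impute='global-minimum'`` replaces missing intensities with the
    smallest observed intensity in the table before testing (mirroring the
    global-imputing option of protein-report software); the default leaves
    missing values missing, so only complete pairs are tested.
    """
    if impute not in ("none", "global-minimum"):
        raise ValueError(f"unknown imputation mode {impute!r}")
    work = median_normalize(table) if normalize else table
    if impute == "global-minimum":
        global_min = np.nanmin(work.to_numpy(dtype=float))
        work = work.fillna(global_min)
    result = paired_log2_contrast(work, design, condition)
    tested = result.table["p_value"].notna()
    if tested.any():
        q = storey_qvalues(result.table.loc[tested, "p_value"].to_numpy(),
                           lam=lam, pi0_override=pi0_override)
        result.table.loc[tested, "q_value"] = q
    result.meta.update({"normalize": normalize, "impute": impute,
                        "lambda": lam, "pi0_override": pi0_override})
    return result
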