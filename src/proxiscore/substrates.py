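"""Substrate discovery from multi-condition enrichment calls.

A protein that interacts with the proteasome only when proteolysis is
blocked behaves like a substrate: stalled on the inhibited complex long
enough to be biotinylated, invisible under vehicle.  The operations here
formalize that logic as set algebra over per-condition enrichment calls:

* the exclusive set — enriched under inhibitor, not under vehicle;
* annotation of candidates against reference lists (UPS membership,
  known substrates, ubiquitylation response) in a fixed priority order;
* a distribution-shift test on log2 fold changes of candidates vs the
  rest of the proteome;
* classification of degrader (PROTAC) experiments into degrader-induced,
  inhibition-dependent, constitutive, or unaffected proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .coelution import wilcoxon_rank_sum

__all__ = [
    "SubstrateReport",
    "enriched_ids",
    "exclusive_enriched_set",
    "annotate_candidates",
    "shift_test",
    "degrader_contrast",
]


@dataclass
class SubstrateReport:
    """Annotation breakdown of an exclusive-enrichment candidate set."""

    exclusive: set[str]
    categories: pd.Series          # protein -> category
    counts: dict[str, int]
    percentages: dict[str, int]    # integer percent, half-up
    ubi_responsive_of_remainder: int = 0
    ubi_responsive_percent: int = 0
    meta: dict = field(default_factory=dict)


def enriched_ids(calls: pd.DataFrame) -> set[str]:
    """Protein ids flagged enriched in a calls table."""
    return set(calls.index[calls["enriched"].astype(bool)])


def _condition_sets(calls: dict, *needed: str) -> dict[str, set]:
    out = {}
    for cond in needed:
        if cond not in calls:
            raise ValueError(f"condition {cond!r} missing from calls "
                             f"(have {sorted(calls)})")
        c = calls[cond]
        out[cond] = enriched_ids(c) if isinstance(c, pd.DataFrame) else set(c)
    return out


def exclusive_enriched_set(calls: dict, treated: str, control: str) -> set[str]:
    """Proteins enriched under ``treated`` but not under ``control``."""
    sets = _condition_sets(calls, treated, control)
    return sets[treated] - sets[control]


def _pct(k: int, n: int) -> int:
    """Integer percent, rounded half-up."""
    if n == 0:
        return 0
    return int((Decimal(100 * k) / Decimal(n)).quantize(Decimal(1), ROUND_HALF_UP))


def annotate_candidates(exclusive, ups_ids=(), substrate_ids=(),
                        ubi_responsive_ids=()) -> SubstrateReport:
    """Categorize an exclusive set against reference annotation lists.

    Priority order (first match wins): proteasome/ubiquitin-related (UPS)
    > known substrate > unannotated candidate.  Within the unannotated
    remainder, proteins on the ubiquitylation-responsive list are flagged
    and reported as a count and integer percentage of the remainder —
    they stay in the candidate category.
    """
    exclusive = set(exclusive)
    ups = set(ups_ids)
    subs = set(substrate_ids)
    ubi = set(ubi_responsive_ids)

    cats = {}
    for pid in exclusive:
        if pid in ups:
            cats[pid] = "proteasome/ubiquitin-related"
        elif pid in subs:
            cats[pid] = "known substrate"
        else:
            cats[pid] = "unannotated-candidate"
    categories = pd.Series(cats, dtype=object)

    counts = {c: int((categories == c).sum())
              for c in ("proteasome/ubiquitin-related", "known substrate",
                        "unannotated-candidate")}
    n = len(exclusive)
    percentages = {c: _pct(k, n) for c, k in counts.items()}
    remainder = [p for p, c in cats.items() if c == "unannotated-candidate"]
    n_ubi = sum(1 for p in remainder if p in ubi)
    return SubstrateReport(
        exclusive=exclusive, categories=categories, counts=counts,
        percentages=percentages,
        ubi_responsive_of_remainder=n_ubi,
        ubi_responsive_percent=_pct(n_ubi, len(remainder)),
        meta={"n_exclusive": n, "n_remainder": len(remainder)},
    )


def shift_test(contrast, candidate_set) -> dict:
    """Are candidate log2 fold changes shifted relative to the rest?

    Wilcoxon rank-sum (continuity-corrected) of the candidates' mean log2
    ratios against all other proteins with a defined ratio; reports the
    group medians and their difference as the effect size.  Run this
    separately on a total-proteome contrast and on the proximity-labeling
    contrast to separate abundance increases from proteasome recruitment.
    """
    ratios = contrast.table["mean_log2_ratio"].dropna()
    candidate_set = set(candidate_set)
    in_set = ratios.index.isin(candidate_set)
    cand = ratios[in_set].to_numpy()
    rest = ratios[~in_set].to_numpy()
    if cand.size < 3 or rest.size < 3:
        raise ValueError(f"need >= 3 proteins with defined log2 ratios per "
                         f"group, got {cand.size} candidates / {rest.size} rest")
    u, p = wilcoxon_rank_sum(cand, rest)
    med_c, med_r = float(np.median(cand)), float(np.median(rest))
    return {
        "n_candidates": int(cand.size),
        "n_rest": int(rest.size),
        "median_candidates": med_c,
        "median_rest": med_r,
        "median_difference": med_c - med_r,
        "statistic": u,
        "p_value": p,
    }


DEGRADER_CLASSES = ("constitutive", "degrader-induced",
                    "inhibition-dependent", "none")


def degrader_contrast(calls: dict, protac: str = "P",
                      protac_inhibitor: str = "P+I",
                      inhibitor: str = "I",
                      untreated: str = "none") -> pd.Series:
    """Classify proteins in a degrader (PROTAC) experiment.

    Requires at least the PROTAC-alone and PROTAC+inhibitor conditions.
    Classes, in priority order:

    * ``constitutive`` — enriched with no treatment at all;
    * ``degrader-induced`` — enriched under the degrader even without
      proteasome inhibition (the signature of an induced target);
    * ``inhibition-dependent`` — enriched only in arms that include the
      inhibitor (substrate-like behavior);
    * ``none`` — never enriched.
    """
    needed = [protac, protac_inhibitor]
    optional = [c for c in (inhibitor, untreated) if c in calls]
    sets = _condition_sets(calls, *needed, *optional)
    p_set = sets[protac]
    pi_set = sets[protac_inhibitor]
    i_set = sets.get(inhibitor, set())
    none_set = sets.get(untreated, set())

    universe = set().union(p_set, pi_set, i_set, none_set)
    for c in calls.values():
        if isinstance(c, pd.DataFrame):
            universe |= set(c.index)

    out = {}
    for pid in universe:
        if pid in none_set:
            out[pid] = "constitutive"
        elif pid in p_set:
            out[pid] = "degrader-induced"
        elif pid in pi_set or pid in i_set:
            out[pid] = "inhibition-dependent"
        else:
            out[pid] = "none"
    return pd.Series(out, dtype=object).sort_index()
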