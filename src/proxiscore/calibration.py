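"""Monte-Carlo calibration of the FPR-targeted classifier threshold.

The deployed decision rule promises a false-positive rate near the target
on proteins that behave like the anchor negatives.  This module measures
that promise directly: simulate pull-down experiments with a pool of
labeled true-negative proteins that are *not* shown to the classifier,
run the full scoring chain, and report the fraction of those held-out
negatives called enriched.  Averaged over replicate simulations, the
held-out FPR should sit at or below the target (the threshold is chosen
on 200 training negatives, so the expected held-out exceedance of the
k-th largest training score is k/201 < k/200).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classifier import (AnchorSets, call_enriched, compute_enrichment_scores,
                         fit_enrichment_classifier)
from .diffabund import run_differential
from .simulate import BioidSimConfig, generate_bioid_dataset

__all__ = ["CALIBRATION_CONFIG", "heldout_fpr", "fpr_calibration"]

# reference simulation conditions for the calibration study: a large null
# background, strong well-separated anchor positives, 200 training and 300
# held-out negatives, four paired replicates with 0.5 log2-units of noise
CALIBRATION_CONFIG = BioidSimConfig(
    n_background=5000, n_anchor_pos=40, n_anchor_neg=200, n_heldout_neg=300,
    anchor_effect_log2=4.0, n_replicates=4, rep_noise_sd=0.5, seed=0)


def heldout_fpr(config: BioidSimConfig, target_fpr: float = 0.05) -> float:
    """Held-out false-positive rate of one simulated experiment.

    Generates the dataset, runs differential abundance and enrichment
    scoring, fits the anchor classifier and its FPR-targeted threshold on
    the training anchors only, then measures the fraction of held-out
    labeled negatives called enriched.
    """
    table, design, truth = generate_bioid_dataset(config)
    contrast = run_differential(table, design, "main")
    scores = compute_enrichment_scores(contrast)
    anchors = AnchorSets(set(truth.proteins_with_label("anchor_pos")),
                         set(truth.proteins_with_label("anchor_neg")))
    fit = fit_enrichment_classifier(scores, anchors, target_fpr=target_fpr,
                                    run_cv=False)
    calls = call_enriched(scores, fit)
    heldout = [p for p in truth.proteins_with_label("heldout_neg")
               if p in calls.index]
    if not heldout:
        raise ValueError("config has no held-out negatives (n_heldout_neg=0)")
    return float(calls.loc[heldout, "enriched"].mean())


def fpr_calibration(seeds, config: BioidSimConfig | None = None,
                    target_fpr: float = 0.05) -> np.ndarray:
    """Held-out FPR for one simulated dataset per seed."""
    base = CALIBRATION_CONFIG if config is None else config
    out = []
    for seed in seeds:
        cfg = dataclasses.replace(base, seed=int(seed))
        out.append(heldout_fpr(cfg, target_fpr=target_fpr))
    return np.array(out)
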