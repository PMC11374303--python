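import pytest

from proxiscore import (AnchorSets, BioidSimConfig, ConditionSpec,
                        generate_bioid_dataset, generate_contrast_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy single-condition pull-down with planted interactors."""
    config = BioidSimConfig(n_background=800, n_anchor_pos=25, n_anchor_neg=60,
                            n_heldout_neg=40, n_planted_interactors=15,
                            effect_log2=3.0, rep_noise_sd=0.5, seed=11)
    table, design, truth = generate_bioid_dataset(config)
    return config, table, design, truth


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Deterministic dataset: ratios equal planted effects exactly."""
    config = BioidSimConfig(n_background=300, n_anchor_pos=20, n_anchor_neg=40,
                            n_planted_interactors=10, effect_log2=2.0,
                            rep_noise_sd=0.0, pair_offset_sd=0.0, seed=5)
    table, design, truth = generate_bioid_dataset(config)
    return config, table, design, truth


@pytest.fixture(scope="session")
def inhibitor_dataset():
    """Noise-free +/- inhibitor design; substrates enriched only under drug."""
    config = BioidSimConfig(n_background=200, n_anchor_pos=15, n_anchor_neg=30,
                            n_planted_interactors=8, n_planted_substrates=12,
                            effect_log2=2.0, rep_noise_sd=0.0, pair_offset_sd=0.0, seed=9)
    conditions = [
        ConditionSpec("vehicle"),
        ConditionSpec("inhibitor", effects={"planted_substrate": 5.0},
                      treatments={"MG132": True}),
    ]
    table, design, truth = generate_contrast_dataset(config, conditions)
    return config, conditions, table, design, truth


@pytest.fixture(scope="session")
def anchors(small_dataset):
    _, _, _, truth = small_dataset
    return AnchorSets(set(truth.proteins_with_label("anchor_pos")),
                      set(truth.proteins_with_label("anchor_neg")))
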