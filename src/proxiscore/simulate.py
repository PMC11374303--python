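"""Synthetic data generation for proximity-labeling experiments.

Every downstream stage of the pipeline (differential abundance, the
anchor-set classifier, SEC co-elution, substrate calling, structural
proximity) is testable against planted ground truth produced here, without
any external mass-spectrometry deposition.

The generative model, briefly:

* Protein abundance is log-normal: each protein draws a baseline log2
  abundance from N(baseline_mean, baseline_sd).
* A bait pull-down sample and its paired ligase-only control share a
  replicate-batch offset drawn once per pair, so paired tests genuinely
  gain power over unpaired ones.
* Planted enrichment effects (in log2 units) are added to bait samples
  only, per ground-truth label and, for multi-condition designs, per
  condition.
* Tables are exponentiated to the linear intensity scale before they are
  handed to readers — downstream operations own the log transform, as with
  real protein reports.
* Missing values are either uniform at random or biased toward
  low-abundance proteins via a logistic curve in baseline log2 abundance.

SEC elution profiles are mixtures of Gaussian peaks over ordered
fractions: shared complex peaks plus a per-protein free (monomeric) pool,
with optional multiplicative log-normal noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BioidSimConfig",
    "ConditionSpec",
    "SecSimConfig",
    "GroundTruth",
    "SecGroundTruth",
    "generate_bioid_dataset",
    "generate_contrast_dataset",
    "generate_sec_dataset",
    "generate_structure_fixture",
]

LABELS = ("anchor_pos", "anchor_neg", "heldout_neg", "planted_interactor",
          "planted_substrate", "background")


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class BioidSimConfig:
    """Configuration for a bait-vs-control pull-down simulation.

    Counts partition the protein universe; effects are log2-scale
    enrichments applied to bait samples only.
    """

    n_background: int = 5000
    n_anchor_pos: int = 40
    n_anchor_neg: int = 200
    n_heldout_neg: int = 0
    n_planted_interactors: int = 0
    n_planted_substrates: int = 0
    effect_log2: float = 2.0
    anchor_effect_log2: float = 4.0
    n_replicates: int = 4
    rep_noise_sd: float = 0.5
    pair_offset_sd: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    missing_rate: float = 0.0
    missing_mode: str = "random"
    missing_midpoint: float | None = None  # default: baseline_mean
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_anchor_pos", "n_anchor_neg",
                     "n_heldout_neg", "n_planted_interactors",
                     "n_planted_substrates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_replicates < 2:
            raise ConfigError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.rep_noise_sd < 0:
            raise ConfigError(f"rep_noise_sd must be >= 0, got {self.rep_noise_sd}")
        if self.pair_offset_sd < 0:
            raise ConfigError(f"pair_offset_sd must be >= 0, got {self.pair_offset_sd}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.missing_mode not in ("random", "low-abundance-biased"):
            raise ConfigError(f"missing_mode must be 'random' or "
                              f"'low-abundance-biased', got {self.missing_mode!r}")
        if self.baseline_sd < 0:
            raise ConfigError(f"baseline_sd must be >= 0, got {self.baseline_sd}")


@dataclass(frozen=True)
class ConditionSpec:
    """One treatment arm of a multi-condition design.

    ``effects`` maps ground-truth labels to the log2 enrichment planted in
    that condition's bait samples; labels not listed get their config
    default (anchors keep anchor_effect_log2 in every condition unless
    overridden).  ``treatments`` are free-form boolean flags recorded in
    the sample design (e.g. {"MG132": True}).
    """

    name: str
    effects: dict[str, float] = field(default_factory=dict)
    treatments: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Planted truth for a simulated pull-down dataset.

    ``labels`` is a Series over the protein universe with values in the
    label vocabulary; ``effects`` has one column per condition holding each
    protein's planted log2 enrichment in that condition.
    """

    labels: pd.Series
    effects: pd.DataFrame

    def proteins_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _universe(config: BioidSimConfig) -> pd.Series:
    ids, labels = [], []
    for label, n, stem in (
        ("anchor_pos", config.n_anchor_pos, "POS"),
        ("anchor_neg", config.n_anchor_neg, "NEG"),
        ("heldout_neg", config.n_heldout_neg, "HNEG"),
        ("planted_interactor", config.n_planted_interactors, "INT"),
        ("planted_substrate", config.n_planted_substrates, "SUB"),
        ("background", config.n_background, "BG"),
    ):
        ids.extend(f"{stem}{i:05d}" for i in range(1, n + 1))
        labels.extend([label] * n)
    if not ids:
        raise ConfigError("n_background: protein universe is empty "
                          "(all counts are zero)")
    return pd.Series(labels, index=pd.Index(ids, name="protein_id"), name="label")


def _default_effects(config: BioidSimConfig, labels: pd.Series) -> pd.Series:
    eff = pd.Series(0.0, index=labels.index)
    eff[labels == "anchor_pos"] = config.anchor_effect_log2
    eff[labels == "planted_interactor"] = config.effect_log2
    return eff


def _missing_mask(config: BioidSimConfig, baseline: np.ndarray,
                  shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    if config.missing_rate == 0:
        return np.zeros(shape, dtype=bool)
    if config.missing_mode == "random":
        p = np.full(shape[0], config.missing_rate)
    else:
        mid = (config.baseline_mean if config.missing_midpoint is None
               else config.missing_midpoint)
        w = 1.0 / (1.0 + np.exp(config.missing_slope * (baseline - mid)))
        # rescale so the marginal missing fraction matches missing_rate
        p = np.clip(config.missing_rate * w / w.mean(), 0.0, 0.999)
    return rng.random(shape) < p[:, None]


def _simulate_condition(config: BioidSimConfig, baseline: np.ndarray,
                        effects: np.ndarray, cond: str,
                        rng: np.random.Generator,
                        treatments: dict[str, bool]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired bait/control intensity block for one condition."""
    n_prot, n_rep = baseline.size, config.n_replicates
    pair_offsets = rng.normal(0.0, config.pair_offset_sd, size=(n_prot, n_rep))
    noise_bait = rng.normal(0.0, config.rep_noise_sd, size=(n_prot, n_rep))
    noise_ctrl = rng.normal(0.0, config.rep_noise_sd, size=(n_prot, n_rep))

    log2_bait = baseline[:, None] + pair_offsets + effects[:, None] + noise_bait
    log2_ctrl = baseline[:, None] + pair_offsets + noise_ctrl

    values = np.concatenate([2.0 ** log2_bait, 2.0 ** log2_ctrl], axis=1)
    mask = np.concatenate(
        [_missing_mask(config, baseline, (n_prot, n_rep), rng),
         _missing_mask(config, baseline, (n_prot, n_rep), rng)], axis=1)
    values = np.where(mask, np.nan, values)

    bait_ids = [f"{cond}_bait_{i}" for i in range(1, n_rep + 1)]
    ctrl_ids = [f"{cond}_ctrl_{i}" for i in range(1, n_rep + 1)]
    rows = []
    for arm, sids in (("bait", bait_ids), ("control", ctrl_ids)):
        for i, sid in enumerate(sids, start=1):
            row = {"sample_id": sid, "condition": cond, "arm": arm,
                   "replicate": i, "pair_id": f"{cond}_pair_{i}"}
            row.update({k: bool(v) for k, v in treatments.items()})
            rows.append(row)
    design = pd.DataFrame(rows).set_index("sample_id")
    table = pd.DataFrame(values, columns=bait_ids + ctrl_ids)
    return table, design


def generate_bioid_dataset(
    config: BioidSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a single-condition paired pull-down experiment.

    Returns a linear-scale intensity table (proteins x samples, NaN where
    missing), a sample design, and the planted :class:`GroundTruth`.
    Identical config (including seed) gives bit-identical output.
    """
    labels = _universe(config)
    rng = np.random.default_rng(config.seed)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, labels.size)
    effects = _default_effects(config, labels)

    table, design = _simulate_condition(
        config, baseline, effects.to_numpy(), "main", rng, {})
    table.index = labels.index
    truth = GroundTruth(labels=labels, effects=effects.to_frame(name="main"))
    return table, design, truth


def generate_contrast_dataset(
    config: BioidSimConfig, conditions: list[ConditionSpec],
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a multi-condition design (e.g. +/- proteasome inhibitor).

    All conditions share the protein universe and per-protein baselines;
    each gets its own paired bait/control block with condition-specific
    planted effects per the :class:`ConditionSpec`.
    """
    if not conditions:
        raise ConfigError("conditions list is empty")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate condition names: {names}")
    labels = _universe(config)
    for spec in conditions:
        unknown = set(spec.effects) - set(LABELS)
        if unknown:
            raise ConfigError(
                f"condition {spec.name!r} references unknown labels: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, labels.size)

    blocks, designs, effect_cols = [], [], {}
    for spec in conditions:
        eff = _default_effects(config, labels)
        for label, value in spec.effects.items():
            eff[labels == label] = value
        effect_cols[spec.name] = eff
        table, design = _simulate_condition(
            config, baseline, eff.to_numpy(), spec.name, rng, spec.treatments)
        blocks.append(table)
        designs.append(design)

    table = pd.concat(blocks, axis=1)
    table.index = labels.index
    design = pd.concat(designs)
    # treatment flags absent in some conditions become explicit False
    flag_cols = [c for c in design.columns
                 if c not in ("condition", "arm", "replicate", "pair_id")]
    for c in flag_cols:
        design[c] = design[c].notna() & design[c].eq(True)
    truth = GroundTruth(labels=labels, effects=pd.DataFrame(effect_cols))
    return table, design, truth


# ---------------------------------------------------------------------------
# SEC elution profiles


@dataclass(frozen=True)
class ComplexSpec:
    """One co-eluting complex: a shared Gaussian peak and its members."""

    peak_fraction: float
    peak_width: float
    members: tuple[str, ...]
    weights: tuple[float, ...] | None = None  # stoichiometry; default equal


@dataclass(frozen=True)
class SecSimConfig:
    n_fractions: int = 32
    complexes: tuple[ComplexSpec, ...] = ()
    free_pool_fraction: float = 0.0
    free_peak_fraction: float | None = None  # default: n_fractions - 2
    free_peak_width: float = 1.5
    n_background_proteins: int = 0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 8:
            raise ConfigError(f"n_fractions must be >= 8, got {self.n_fractions}")
        for cx in self.complexes:
            if cx.peak_width <= 0:
                raise ConfigError(f"peak_width must be > 0, got {cx.peak_width}")
            if not (1 <= cx.peak_fraction <= self.n_fractions):
                raise ConfigError(
                    f"peak_fraction {cx.peak_fraction} outside [1, {self.n_fractions}]")
            if cx.weights is not None and len(cx.weights) != len(cx.members):
                raise ConfigError(f"weights length mismatch for complex at "
                                  f"fraction {cx.peak_fraction}")
        if not (0 <= self.free_pool_fraction <= 1):
            raise ConfigError(
                f"free_pool_fraction must be in [0, 1], got {self.free_pool_fraction}")
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")


@dataclass
class SecGroundTruth:
    """Noise-free construction truth for a simulated SEC run."""

    clean_profiles: pd.DataFrame           # proteins x fractions, rows sum to 1
    membership: dict[str, list[int]]       # protein -> indices into config.complexes
    config: SecSimConfig

    def expected_window_fraction(self, protein_id: str,
                                 windows: list[tuple[int, int]]) -> float:
        """Noise-free signal fraction inside the union of fraction windows."""
        profile = self.clean_profiles.loc[protein_id]
        keep = set()
        for start, stop in windows:
            keep.update(range(start, stop + 1))
        cols = [f for f in self.clean_profiles.columns if f in keep]
        return float(profile[cols].sum())


def _gaussian_profile(fractions: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    g = np.exp(-0.5 * ((fractions - mu) / sigma) ** 2)
    return g / g.sum()


def generate_sec_dataset(config: SecSimConfig) -> tuple[pd.DataFrame, SecGroundTruth]:
    """Simulate a size-exclusion chromatography quantity table.

    Each member's clean profile allocates ``free_pool_fraction`` of its
    mass to a late monomer peak and the rest across its complexes'
    Gaussian peaks (by stoichiometry weight).  Multiplicative log-normal
    noise with coefficient of variation ``noise_cv`` is then applied; at
    noise_cv=0 the output equals the clean construction exactly.
    """
    fractions = np.arange(1, config.n_fractions + 1, dtype=float)
    free_mu = (config.n_fractions - 2 if config.free_peak_fraction is None
               else config.free_peak_fraction)
    free_peak = _gaussian_profile(fractions, free_mu, config.free_peak_width)

    membership: dict[str, list[int]] = {}
    weight_of: dict[str, dict[int, float]] = {}
    for k, cx in enumerate(config.complexes):
        w = cx.weights if cx.weights is not None else tuple([1.0] * len(cx.members))
        for m, wi in zip(cx.members, w):
            membership.setdefault(m, []).append(k)
            weight_of.setdefault(m, {})[k] = float(wi)

    rng = np.random.default_rng(config.seed)
    for i in range(1, config.n_background_proteins + 1):
        pid = f"SECBG{i:05d}"
        mu = rng.uniform(2, config.n_fractions - 1)
        width = rng.uniform(0.8, 2.5)
        membership.setdefault(pid, [])
        weight_of.setdefault(pid, {})
        weight_of[pid][-i] = (mu, width)  # private peak, keyed negatively

    profiles = {}
    for pid, cxs in membership.items():
        clean = config.free_pool_fraction * free_peak
        own = 1.0 - config.free_pool_fraction
        shared = {k: v for k, v in weight_of[pid].items() if k >= 0}
        private = {k: v for k, v in weight_of[pid].items() if k < 0}
        total_w = sum(shared.values()) + len(private)
        for k, wi in shared.items():
            cx = config.complexes[k]
            clean = clean + own * (wi / total_w) * _gaussian_profile(
                fractions, cx.peak_fraction, cx.peak_width)
        for _, (mu, width) in private.items():
            clean = clean + own * (1.0 / total_w) * _gaussian_profile(
                fractions, mu, width)
        profiles[pid] = clean

    cols = [int(f) for f in fractions]
    clean_df = pd.DataFrame.from_dict(profiles, orient="index", columns=cols)
    clean_df.index.name = "protein_id"

    abundance = 2.0 ** rng.normal(20.0, 1.5, size=clean_df.shape[0])
    values = clean_df.to_numpy() * abundance[:, None]
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=values.shape)
        values = values * noise
    run = pd.DataFrame(values, index=clean_df.index, columns=cols)
    truth = SecGroundTruth(clean_profiles=clean_df, membership=membership,
                           config=config)
    return run, truth


# ---------------------------------------------------------------------------
# Structure fixtures


def generate_structure_fixture(
    n_within: int, n_outside: int, radius_A: float, seed: int = 0,
) -> tuple["pd.DataFrame", pd.DataFrame, np.ndarray]:
    """Synthetic structure fixture for the proximity-radius check.

    Builds an atom table with a short bait chain A whose C-terminal Calpha
    sits at the origin (the anchor), and a site chain B of lysines whose
    side-chain NZ atoms are placed strictly inside (n_within) or strictly
    outside (n_outside) a sphere of ``radius_A`` angstroms.  Returns the
    atom table, a site list (chain, residue_number, residue_name), and the
    boolean construction truth (True = within).  This is a synthetic
    fixture, not a real macromolecular model: site CA and NZ coordinates
    coincide.
    """
    if n_within < 0 or n_outside < 0:
        raise ConfigError(f"site counts must be >= 0, got "
                          f"n_within={n_within}, n_outside={n_outside}")
    if radius_A <= 0:
        raise ConfigError(f"radius_A must be > 0, got {radius_A}")
    rng = np.random.default_rng(seed)

    atoms = []
    # bait chain: three glycines marching toward the origin; last CA = anchor
    for resnum, x in ((1, -10.0), (2, -5.0), (3, 0.0)):
        atoms.append(("A", resnum, "GLY", "CA", x, 0.0, 0.0))

    n_sites = n_within + n_outside
    radii = np.concatenate([
        radius_A * rng.uniform(0.10, 0.95, size=n_within),
        radius_A * rng.uniform(1.05, 2.00, size=n_outside),
    ])
    truth = np.concatenate([np.ones(n_within, bool), np.zeros(n_outside, bool)])
    direction = rng.normal(size=(n_sites, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    points = direction / norms * radii[:, None]

    sites = []
    for i in range(n_sites):
        x, y, z = points[i]
        atoms.append(("B", i + 1, "LYS", "CA", float(x), float(y), float(z)))
        atoms.append(("B", i + 1, "LYS", "NZ", float(x), float(y), float(z)))
        sites.append({"chain": "B", "residue_number": i + 1,
                      "residue_name": "LYS"})

    atom_df = pd.DataFrame(
        atoms, columns=["chain", "residue_number", "residue_name",
                        "atom_name", "x", "y", "z"])
    site_df = pd.DataFrame(sites, columns=["chain", "residue_number",
                                           "residue_name"])
    return atom_df, site_df, truth


def atoms_to_pdb(atoms: pd.DataFrame) -> str:
    """Serialize an atom table as minimal PDB-format text."""
    lines = []
    serial = 0
    for _, a in atoms.iterrows():
        serial += 1
        name = str(a.atom_name)
        padded = name if len(name) >= 4 else f" {name:<3s}"
        element = name[0]
        lines.append(
            f"ATOM  {serial:5d} {padded} {a.residue_name:>3s} "
            f"{a.chain}{int(a.residue_number):4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"
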