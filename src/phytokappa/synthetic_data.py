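"""Synthetic study generator with planted ground truth.

The study emulated here profiles ~87 plant species: an LC-MS feature table
(thousands of peaks per species), triplicate agar-diffusion inhibition
radii against a bacterial tester strain, triplicate MTT absorbances for two
mammalian cell lines plus a solvent control, and a rooted phylogeny of the
species.  Because no machine-readable feature matrix is publicly deposited
for such studies, every downstream stage is exercised on synthetic data
with known ground truth:

* *causal* single features present (up to label-flip noise) exactly in the
  antimicrobially active species;
* *synergy* (AND) pairs: two components that are individually weak raters
  but whose profile intersection equals the active set;
* *redundancy* (OR) pairs: two components covering disjoint halves of the
  active set, so their union equals it;
* independent Bernoulli background features.

Trees come from a unit-rate Yule pure-birth process; binary traits are laid
on them either by thresholded Brownian motion (phylogenetically clumped,
D ~ 0) or uniformly at random (D ~ 1).
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .feature_table import INTENSITY_THRESHOLD, PeakTable
from .phylo_signal import _IndexedTree, threshold_at_prevalence

CELL_LINES = ("HaCaT", "IEC-6")


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study; ``seed`` fully determines the output.

    Intensity means are log10 units: present peaks draw around
    ``intensity_log_mean_present`` (default 1e5, comfortably above the 1e4
    presence threshold), absent peaks around ``intensity_log_mean_absent``.
    ``effect_radius_cm`` is the mean inhibition radius of active species
    (>= the 0.6 cm classification threshold); inactive species centre at
    ``inactive_radius_cm``.  Cytotoxic species have treated-cell absorbance
    scaled to ``cytotoxic_viability`` of the solvent control.
    """

    n_species: int = 87
    n_features: int = 2000
    background_prevalence: float = 0.2
    n_causal_single: int = 1
    n_synergy_pairs: int = 1
    n_redundancy_pairs: int = 1
    flip_noise: float = 0.05
    active_fraction: float = 17 / 87
    intensity_log_mean_present: float = 5.0
    intensity_log_mean_absent: float = 2.5
    intensity_log_sd: float = 0.3
    replicates: int = 3
    effect_radius_cm: float = 0.9
    inactive_radius_cm: float = 0.2
    radius_sd_cm: float = 0.05
    control_absorbance: float = 1.0
    absorbance_sd: float = 0.05
    cytotoxic_viability: float = 0.5
    cytotoxic_fraction_hacat: float = 0.02
    cytotoxic_fraction_iec6: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        planted = self.n_causal_single + 2 * (self.n_synergy_pairs + self.n_redundancy_pairs)
        if planted > self.n_features:
            raise ValueError("planted features exceed n_features")
        if not 0 < self.background_prevalence < 1:
            raise ValueError("background_prevalence must lie in (0, 1)")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for within-group variance")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study: what a perfect analysis should recover."""

    causal_feature_ids: list = field(default_factory=list)
    synergy_pairs: list = field(default_factory=list)
    redundancy_pairs: list = field(default_factory=list)
    true_activity: dict = field(default_factory=dict)
    true_cytotoxicity: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def species_ids(n: int) -> list[str]:
    return [f"sp_{i + 1:03d}" for i in range(n)]


def generate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Rooted, strictly bifurcating Yule (pure-birth, unit-rate) tree.

    Tip labels are ``sp_001``.. so they match the per-species tables.
    The same (n_species, seed) always yields the same Newick string.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    from dendropy.simulate import treesim

    rng = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    labels = species_ids(n_species)
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon.label = label
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length is None or edge.length <= 0):
            edge.length = 1e-8
    return tree


def simulate_binary_trait(
    tree: dendropy.Tree,
    mode: str,
    prevalence: float,
    seed: int,
) -> pd.Series:
    """Binary trait on the tips with exactly ceil(prevalence * n) ones.

    ``brownian_threshold``: Brownian motion on the branches (variance
    proportional to branch length), thresholded at the sample quantile
    matching the prevalence — phylogenetically clumped (D ~ 0).
    ``random``: a uniform random subset of tips — no signal (D ~ 1).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    indexed = tree if isinstance(tree, _IndexedTree) else _IndexedTree(tree)
    n = indexed.n_tips
    k = int(np.ceil(prevalence * n))
    if k == 0 or k == n:
        raise ValueError(f"prevalence {prevalence} yields a monomorphic trait on {n} tips")
    rng = np.random.default_rng(seed)
    if mode == "random":
        state = np.zeros(n, dtype=int)
        state[rng.choice(n, size=k, replace=False)] = 1
    elif mode == "brownian_threshold":
        tips = indexed.simulate_brownian_tips(1, rng)
        state = threshold_at_prevalence(tips, k)[0].astype(int)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(state, index=indexed.tip_labels, name="trait")


def _flip(state: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p == 0:
        return state.copy()
    return np.where(rng.random(state.size) < p, 1 - state, state)


def _feature_metadata(feature_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Unique (m/z, rt) pairs at reporting precision (2 dp / 1 dp)."""
    n = len(feature_ids)
    seen: set[tuple[float, float]] = set()
    mz = np.empty(n)
    rt = np.empty(n)
    for i in range(n):
        while True:
            pair = (round(float(rng.uniform(100, 1000)), 2), round(float(rng.uniform(1, 80)), 1))
            if pair not in seen:
                seen.add(pair)
                mz[i], rt[i] = pair
                break
    return pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id"))


def generate_peak_table(
    config: SyntheticConfig,
    activity,
) -> tuple[PeakTable, SyntheticTruth]:
    """Feature matrix with planted causal / synergy / redundancy structure.

    ``activity`` is the binary antimicrobial ground truth per species (Series
    or array of length n_species).  Causal features copy the activity vector
    with independent per-species flips at ``flip_noise``.  For an AND pair the
    active set is noise-flipped once, then component A covers it plus one half
    of the inactive species and component B the other half, so the
    intersection reproduces the (flipped) active set while each component
    alone is a weak rater.  For an OR pair the (flipped) active set is split
    into two disjoint halves covered by one component each.  Background
    features are independent Bernoulli(``background_prevalence``).  No feature
    is ever present in all species.
    """
    config.validate()
    activity = pd.Series(activity)
    if len(activity) != config.n_species:
        raise ValueError("activity length must equal n_species")
    act = activity.to_numpy(dtype=int)
    if act.sum() == 0:
        raise ValueError("active set is empty; planting infeasible")
    sp_ids = (
        list(activity.index)
        if not isinstance(activity.index, pd.RangeIndex)
        else species_ids(config.n_species)
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n, F = config.n_species, config.n_features

    presence = np.zeros((F, n), dtype=int)
    truth = SyntheticTruth(true_activity={s: int(v) for s, v in zip(sp_ids, act)})

    feature_ids = [f"ft_{i + 1:05d}" for i in range(F)]
    # planted features occupy random distinct rows
    n_planted = config.n_causal_single + 2 * (config.n_synergy_pairs + config.n_redundancy_pairs)
    slots = rng.choice(F, size=n_planted, replace=False)
    cursor = 0

    for _ in range(config.n_causal_single):
        row = slots[cursor]; cursor += 1
        presence[row] = _flip(act, config.flip_noise, rng)
        truth.causal_feature_ids.append(feature_ids[row])

    for _ in range(config.n_synergy_pairs):
        ra, rb = slots[cursor], slots[cursor + 1]; cursor += 2
        target = _flip(act, config.flip_noise, rng)
        inactive = np.flatnonzero(target == 0)
        if target.sum() == 0 or inactive.size < 2:
            raise ValueError("planting infeasible: need a non-trivial active set")
        inactive = rng.permutation(inactive)
        half = inactive.size // 2
        comp_a, comp_b = target.copy(), target.copy()
        comp_a[inactive[:half]] = 1
        comp_b[inactive[half:]] = 1
        presence[ra], presence[rb] = comp_a, comp_b
        truth.synergy_pairs.append(sorted([feature_ids[ra], feature_ids[rb]]))

    for _ in range(config.n_redundancy_pairs):
        ra, rb = slots[cursor], slots[cursor + 1]; cursor += 2
        target = _flip(act, config.flip_noise, rng)
        ones = np.flatnonzero(target == 1)
        if ones.size < 2:
            raise ValueError("planting infeasible: active set too small to split")
        ones = rng.permutation(ones)
        half = ones.size // 2
        comp_a = np.zeros(n, dtype=int)
        comp_b = np.zeros(n, dtype=int)
        comp_a[ones[:half]] = 1
        comp_b[ones[half:]] = 1
        presence[ra], presence[rb] = comp_a, comp_b
        truth.redundancy_pairs.append(sorted([feature_ids[ra], feature_ids[rb]]))

    background = np.setdiff1d(np.arange(F), slots[:cursor])
    presence[background] = (rng.random((background.size, n)) < config.background_prevalence).astype(int)

    # the ubiquitous-peak filter must never fire on synthetic data
    all_present = presence.all(axis=1)
    for row in np.flatnonzero(all_present):
        presence[row, rng.integers(n)] = 0

    log_int = np.where(
        presence == 1,
        rng.normal(config.intensity_log_mean_present, config.intensity_log_sd, size=(F, n)),
        rng.normal(config.intensity_log_mean_absent, config.intensity_log_sd, size=(F, n)),
    )
    intensity = 10.0 ** log_int
    # guarantee the presence call survives binarization at the standard threshold
    intensity = np.where(
        presence == 1,
        np.maximum(intensity, INTENSITY_THRESHOLD),
        np.minimum(intensity, INTENSITY_THRESHOLD * (1 - 1e-9)),
    )

    features = _feature_metadata(feature_ids, rng)
    table = PeakTable(
        features=features,
        intensity=pd.DataFrame(
            intensity.T, index=pd.Index(sp_ids, name="species_id"), columns=feature_ids
        ),
    )
    return table, truth


def generate_bioassays(
    config: SyntheticConfig,
    activity,
    cytotoxicity: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate bioassay readings consistent with the ground-truth labels.

    Returns ``(inhibition, viability)``.  Inhibition radii (cm) draw from a
    normal around ``effect_radius_cm`` (active) or ``inactive_radius_cm``
    (inactive), truncated at 0.  MTT absorbances draw around the control
    level, scaled by ``cytotoxic_viability`` for cytotoxic species; the
    solvent-control row is shared per cell line.
    """
    config.validate()
    activity = pd.Series(activity)
    act = activity.to_numpy(dtype=int)
    sp_ids = (
        list(activity.index)
        if not isinstance(activity.index, pd.RangeIndex)
        else species_ids(config.n_species)
    )
    if len(act) != config.n_species:
        raise ValueError("activity length must equal n_species")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    K = config.replicates
    rep_cols = [f"rep{i + 1}" for i in range(K)]

    means = np.where(act == 1, config.effect_radius_cm, config.inactive_radius_cm)
    radii = np.maximum(rng.normal(means[:, None], config.radius_sd_cm, size=(len(act), K)), 0.0)
    inhibition = pd.DataFrame(radii, columns=rep_cols)
    inhibition.insert(0, "species_id", sp_ids)

    rows = []
    for line in CELL_LINES:
        cyto = pd.Series(cytotoxicity[line]).reindex(sp_ids).to_numpy(dtype=int)
        control = rng.normal(config.control_absorbance, config.absorbance_sd, size=K)
        rows.append({"species_id": "control", "cell_line": line, "role": "control",
                     **dict(zip(rep_cols, control))})
        mean_abs = np.where(
            cyto == 1,
            config.control_absorbance * config.cytotoxic_viability,
            config.control_absorbance,
        )
        treated = np.maximum(
            rng.normal(mean_abs[:, None], config.absorbance_sd, size=(len(sp_ids), K)), 1e-6
        )
        for sp, reps in zip(sp_ids, treated):
            rows.append({"species_id": sp, "cell_line": line, "role": "treated",
                         **dict(zip(rep_cols, reps))})
    viability = pd.DataFrame(rows)
    return inhibition, viability


@dataclass
class StudyData:
    """One complete synthetic study: everything the pipeline consumes."""

    tree: dendropy.Tree
    peak_table: PeakTable
    inhibition: pd.DataFrame
    viability: pd.DataFrame
    truth: SyntheticTruth


def simulate_study(config: SyntheticConfig, activity_mode: str = "brownian_threshold") -> StudyData:
    """Generate a full study from one config.

    Antimicrobial activity is laid on the tree with ``activity_mode``
    (clumped by default, mirroring a trait concentrated in one clade);
    cytotoxicity labels are phylogenetically random for both cell lines.
    """
    config.validate()
    tree = generate_tree(config.n_species, seed=config.seed)
    activity = simulate_binary_trait(
        tree, activity_mode, config.active_fraction, seed=config.seed + 1
    )
    cytotox = {}
    for i, (line, frac) in enumerate(
        zip(CELL_LINES, (config.cytotoxic_fraction_hacat, config.cytotoxic_fraction_iec6))
    ):
        cytotox[line] = simulate_binary_trait(tree, "random", frac, seed=config.seed + 2 + i)
    table, truth = generate_peak_table(config, activity)
    truth.true_cytotoxicity = {
        line: {s: int(v) for s, v in lab.items()} for line, lab in cytotox.items()
    }
    inhibition, viability = generate_bioassays(config, activity, cytotox)
    return StudyData(tree=tree, peak_table=table, inhibition=inhibition,
                     viability=viability, truth=truth)
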