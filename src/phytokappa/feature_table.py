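"""LC-MS feature-table container, I/O, binarization, filtering and PCA overview.

A *feature* (peak) is a signal uniquely identified by its mass-to-charge
ratio (m/z) and retention time; the table holds one intensity column per
species sample.  Downstream screening operates on presence/absence calls at
a fixed intensity threshold (10^4 by default), after discarding peaks
common to every sample (they carry no discriminative information between
active and inactive species).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: default presence threshold on raw LC-MS intensity
INTENSITY_THRESHOLD = 1e4


@dataclass
class PeakTable:
    """Species x feature intensity matrix with per-feature m/z and retention time.

    ``features``: DataFrame indexed by feature_id with columns ``mz`` (reported
    to 2 decimals) and ``rt`` (minutes).  ``intensity``: DataFrame indexed by
    species_id, one column per feature_id, non-negative; absent = 0.
    """

    features: pd.DataFrame
    intensity: pd.DataFrame

    def __post_init__(self) -> None:
        self.features.index.name = "feature_id"
        self.intensity.columns.name = "feature_id"
        self.intensity.index.name = "species_id"
        if list(self.features.index) != list(self.intensity.columns):
            raise ValueError("feature ids of metadata and intensity matrix disagree")
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValueError(f"duplicate feature_id: {dup!r}")
        if self.intensity.index.duplicated().any():
            dup = self.intensity.index[self.intensity.index.duplicated()][0]
            raise ValueError(f"duplicate species_id: {dup!r}")
        pairs = list(zip(self.features["mz"], self.features["rt"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (mz, rt) pair in feature metadata")
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("retention time must be non-negative")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def species_ids(self) -> list:
        return list(self.intensity.index)

    @property
    def feature_ids(self) -> list:
        return list(self.features.index)

    @property
    def n_species(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensity.shape[1]


@dataclass
class BinaryPeakMatrix:
    """Presence/absence calls (species x feature) at a recorded intensity threshold."""

    presence: pd.DataFrame
    threshold_used: float = INTENSITY_THRESHOLD
    removed_ubiquitous: list = field(default_factory=list)

    @property
    def species_ids(self) -> list:
        return list(self.presence.index)

    @property
    def feature_ids(self) -> list:
        return list(self.presence.columns)


def read_peak_table(path) -> PeakTable:
    """Read a peaks CSV: columns feature_id, mz, rt, then one column per species.

    Non-numeric intensity cells are reported with their line number; missing
    cells are coded 0 (absent) with a logged warning.
    """
    raw = pd.read_csv(path, dtype={"feature_id": str})
    required = ["feature_id", "mz", "rt"]
    if list(raw.columns[:3]) != required:
        raise ValueError(f"first three columns must be {required}, got {list(raw.columns[:3])}")
    if raw["feature_id"].duplicated().any():
        dup = raw["feature_id"][raw["feature_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate feature_id: {dup!r}")
    species_cols = list(raw.columns[3:])
    bad_lines = []
    for col in ["mz", "rt"] + species_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            # +2: one for the header, one for 0-based indexing
            bad_lines.extend((int(i) + 2, col) for i in raw.index[bad])
        raw[col] = coerced
    if bad_lines:
        detail = "; ".join(f"line {ln} column {col!r}" for ln, col in bad_lines[:10])
        raise ValueError(f"non-numeric values: {detail}")
    n_missing = int(raw[species_cols].isna().sum().sum())
    if n_missing:
        logger.warning("%d missing intensity cell(s) coded as 0 (absent)", n_missing)
        raw[species_cols] = raw[species_cols].fillna(0.0)
    features = raw.set_index("feature_id")[["mz", "rt"]]
    intensity = raw.set_index("feature_id")[species_cols].T
    intensity.index.name = "species_id"
    return PeakTable(features=features, intensity=intensity)


def write_peak_table(table: PeakTable, path) -> None:
    """Write the peaks CSV dialect read by :func:`read_peak_table`."""
    out = table.features.copy()
    out.insert(0, "feature_id", out.index)
    for sp in table.species_ids:
        out[sp] = table.intensity.loc[sp].to_numpy()
    out.to_csv(path, index=False)


def binarize(table: PeakTable, threshold: float = INTENSITY_THRESHOLD) -> BinaryPeakMatrix:
    """Presence call: intensity >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return BinaryPeakMatrix(presence=table.intensity >= threshold, threshold_used=threshold)


def filter_ubiquitous(matrix: BinaryPeakMatrix) -> BinaryPeakMatrix:
    """Discard every peak present in ALL species; removed ids are recorded.

    A ubiquitous peak agrees identically with every classification margin and
    carries no contrast; it also makes kappa undefined.  Idempotent.
    """
    presence = matrix.presence
    if presence.shape[0] == 0 or presence.shape[1] == 0:
        return BinaryPeakMatrix(presence.copy(), matrix.threshold_used, list(matrix.removed_ubiquitous))
    ubiquitous = presence.all(axis=0)
    removed = list(presence.columns[ubiquitous])
    if removed:
        logger.info("discarding %d peak(s) common to all samples", len(removed))
    return BinaryPeakMatrix(
        presence=presence.loc[:, ~ubiquitous],
        threshold_used=matrix.threshold_used,
        removed_ubiquitous=list(matrix.removed_ubiquitous) + removed,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_features: list


def pareto_scale(X: np.ndarray) -> np.ndarray:
    """Mean-centre each column, then divide by the square root of its SD (ddof=1)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    return (X - X.mean(axis=0)) / np.sqrt(sd)


def pca_pareto(table: PeakTable, n_components: int = 2, use_binary: bool = False,
               threshold: float = INTENSITY_THRESHOLD) -> PCAResult:
    """PCA of the feature matrix after centring and Pareto scaling.

    Pareto scaling (x - mean)/sqrt(sd) is the metabolomics-standard compromise
    between unit-variance scaling and no scaling: it damps the dominance of
    high-intensity peaks without blowing up noise-level ones.  Zero-variance
    columns are dropped with a warning.  Raw intensities are used by default;
    ``use_binary`` switches to presence/absence at ``threshold``.
    """
    if table.n_species < 2:
        raise ValueError("PCA needs at least 2 species")
    X = table.intensity.to_numpy(dtype=float)
    if use_binary:
        X = (X >= threshold).astype(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s) before PCA", stacklevel=2)
    X = X[:, keep]
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xs = pareto_scale(X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.intensity.index, columns=pcs),
        loadings=pd.DataFrame(pca.components_.T, index=kept_ids, columns=pcs),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_features=dropped,
    )


@dataclass
class GroupEllipse:
    """Two-standard-deviational ellipse of a group's first two score coordinates."""

    group: object
    center: np.ndarray
    half_axes: np.ndarray  # 2 * sqrt(eigenvalues of the 2x2 covariance)
    angle_deg: float


def group_ellipse(scores: pd.DataFrame, grouping: pd.Series) -> dict:
    """2-SD ellipse per group from the mean and covariance of its (PC1, PC2) scores.

    Groups with fewer than 3 members get no ellipse (covariance unstable);
    a warning is issued instead.
    """
    grouping = grouping.reindex(scores.index)
    if grouping.isna().any():
        missing = list(scores.index[grouping.isna()])
        raise ValueError(f"grouping does not cover species: {missing}")
    out = {}
    for grp, members in scores.groupby(grouping, observed=True):
        if len(members) < 3:
            warnings.warn(f"group {grp!r} has < 3 members; no ellipse", stacklevel=2)
            continue
        xy = members.iloc[:, :2].to_numpy()
        center = xy.mean(axis=0)
        cov = np.cov(xy, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        out[grp] = GroupEllipse(
            group=grp,
            center=center,
            half_axes=2.0 * np.sqrt(np.maximum(evals, 0.0)),
            angle_deg=angle,
        )
    return out


def chemical_diversity(matrix: BinaryPeakMatrix, grouping) -> pd.DataFrame:
    """Per-group chemical diversity: feature counts per species and distinct totals.

    ``grouping`` maps every species id to a group (e.g. subgenus).  Returns one
    row per group with the species count, mean and median number of present
    features per species, and the number of distinct features present in the
    group.
    """
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    species = set(matrix.species_ids)
    unknown = set(grouping.index) - species
    if unknown:
        raise ValueError("grouping references unknown species: " + ", ".join(sorted(map(str, unknown))))
    uncovered = species - set(grouping.index)
    if uncovered:
        raise ValueError("grouping does not cover species: " + ", ".join(sorted(map(str, uncovered))))
    rows = []
    for grp, ids in sorted(grouping.groupby(grouping).groups.items(), key=lambda kv: str(kv[0])):
        sub = matrix.presence.loc[list(ids)]
        per_species = sub.sum(axis=1)
        rows.append(
            {
                "group": grp,
                "n_species": sub.shape[0],
                "mean_features_per_species": float(per_species.mean()),
                "median_features_per_species": float(per_species.median()),
                "total_distinct_features": int(sub.any(axis=0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def format_feature_label(mz: float, rt: float) -> str:
    """Render a feature as reported: m/z to 2 decimals, rt (min) to 1 decimal."""
    return f"{mz:.2f} @ {rt:.1f} min"
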