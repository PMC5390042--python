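"""Bioassay readings -> binary bioactivity classifications.

Three classifications act as "raters" for the downstream agreement screen:

* antimicrobial (AM): a species is active when its mean agar-diffusion
  inhibition-zone radius is >= 0.6 cm (ties at the threshold are active);
* cytotoxicity toward each of two mammalian cell lines (HaCaT keratinocytes,
  IEC-6 intestinal epithelial cells): per species, MTT absorbances of
  treated cells are compared against the solvent control by a two-group
  one-way ANOVA, p-values are Benjamini-Hochberg corrected across species
  within a cell line, and a species is cytotoxic when the corrected call is
  significant AND mean viability is below 100 %.  A significant reading
  above 100 % indicates hyper-proliferation, not cytotoxicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kappa_screen import benjamini_hochberg

logger = logging.getLogger(__name__)

RADIUS_THRESHOLD_CM = 0.6
CELL_LINES = ("HaCaT", "IEC-6")
CONTROL_ID = "control"


@dataclass
class ActivityLabels:
    """Binary activity calls per species for each assay, with provenance thresholds.

    ``labels``: boolean DataFrame indexed by species id with columns among
    {"AM", "HaCaT", "IEC-6"}.  ``thresholds`` records the radius cut-off and
    the FDR level actually used.
    """

    labels: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def get(self, assay: str) -> pd.Series:
        if assay not in self.labels.columns:
            raise KeyError(f"no labels for assay {assay!r}")
        return self.labels[assay].astype(bool)

    @property
    def species_ids(self) -> list:
        return list(self.labels.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format (species_id, assay, label) table for the labels CSV."""
        rows = []
        for assay in self.labels.columns:
            for sp, val in self.labels[assay].items():
                rows.append({"species_id": sp, "assay": assay,
                             "label": "active" if val else "inactive"})
        return pd.DataFrame(rows)


def viability_percent(absorbance_treated, absorbance_control) -> float:
    """Cell viability in percent: 100 * mean(A_treated) / mean(A_control).

    Values above 100 % indicate induction of hyper-proliferation rather than
    cytotoxicity; values below 100 % indicate compound-induced cell death or
    reduced proliferation.
    """
    treated = np.asarray(absorbance_treated, dtype=float)
    control = np.asarray(absorbance_control, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control absorbance mean must be positive")
    return 100.0 * treated.mean() / control.mean()


def _replicate_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c.startswith("rep")]


def classify_antimicrobial(
    inhibition: pd.DataFrame,
    radius_threshold_cm: float = RADIUS_THRESHOLD_CM,
    species: list | None = None,
) -> pd.DataFrame:
    """Classify species as antimicrobially active from replicate inhibition radii.

    ``inhibition`` has a ``species_id`` column plus replicate columns
    ``rep1..repK`` (radii in cm).  Active iff the replicate mean is >= the
    threshold (results are reported as mean values; ties resolve to active).
    If ``species`` is given, every listed species must be measured.
    """
    reps = _replicate_columns(inhibition)
    if not reps:
        raise ValueError("no replicate columns (rep1..repK) found")
    if species is not None:
        missing = sorted(set(species) - set(inhibition["species_id"]))
        if missing:
            raise ValueError("missing inhibition measurements for species: " + ", ".join(missing))
    radii = inhibition[reps].to_numpy(dtype=float)
    if (radii < 0).any():
        raise ValueError("inhibition radii must be non-negative")
    mean_radius = radii.mean(axis=1)
    return pd.DataFrame(
        {
            "species_id": inhibition["species_id"].to_numpy(),
            "mean_radius_cm": mean_radius,
            "active": mean_radius >= radius_threshold_cm,
        }
    )


def classify_cytotoxicity(
    viability: pd.DataFrame,
    cell_line: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species cytotoxicity call for one cell line.

    ``viability`` is long-format: columns ``species_id, cell_line, role``
    (role in {treated, control}) plus replicate absorbance columns
    ``rep1..repK``; the control rows hold the solvent-control readings shared
    by all species of that cell line.

    Per species a two-group one-way ANOVA (treated vs control absorbances)
    gives a p-value; Benjamini-Hochberg correction runs across all species of
    the cell line; cytotoxic iff BH-significant AND mean viability < 100 %.
    Species with zero variance in both groups have an undefined F statistic:
    they are flagged (``defined`` False) and treated as not significant.
    """
    sub = viability[viability["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"no measurements for cell line {cell_line!r}")
    reps = _replicate_columns(sub)
    control_rows = sub[sub["role"] == "control"]
    if control_rows.empty:
        raise ValueError(f"no solvent-control rows for cell line {cell_line!r}")
    control = control_rows[reps].to_numpy(dtype=float).ravel()
    if control.size < 2:
        raise ValueError("need >= 2 control replicates")
    treated = sub[sub["role"] == "treated"]
    rows = []
    for _, row in treated.iterrows():
        a_treated = row[reps].to_numpy(dtype=float)
        if a_treated.size < 2:
            raise ValueError(f"need >= 2 replicates for species {row['species_id']!r}")
        viab = viability_percent(a_treated, control)
        if np.var(a_treated) == 0 and np.var(control) == 0:
            f, p, defined = np.nan, np.nan, False
        else:
            f, p = stats.f_oneway(a_treated, control)
            defined = bool(np.isfinite(p))
        rows.append(
            {
                "species_id": row["species_id"],
                "viability_percent": viab,
                "hyperproliferative": viab > 100.0,
                "F": f if defined else np.nan,
                "p_value": p if defined else np.nan,
                "defined": defined,
            }
        )
    out = pd.DataFrame(rows)
    p_for_bh = out["p_value"].fillna(1.0).to_numpy()
    reject, p_adj = benjamini_hochberg(p_for_bh, alpha=alpha)
    out["p_adj"] = np.where(out["defined"], p_adj, np.nan)
    out["significant"] = reject & out["defined"].to_numpy()
    out["cytotoxic"] = out["significant"] & (out["viability_percent"] < 100.0)
    return out


def build_activity_labels(
    inhibition: pd.DataFrame,
    viability: pd.DataFrame,
    radius_threshold_cm: float = RADIUS_THRESHOLD_CM,
    alpha: float = 0.05,
) -> tuple[ActivityLabels, dict]:
    """Run all three classifications and assemble the label table.

    Returns the :class:`ActivityLabels` plus the per-assay detail tables
    (statistics and adjusted p-values) keyed by assay name.
    """
    am = classify_antimicrobial(inhibition, radius_threshold_cm)
    details = {"AM": am}
    labels = pd.DataFrame(index=pd.Index(am["species_id"], name="species_id"))
    labels["AM"] = am.set_index("species_id")["active"]
    for line in CELL_LINES:
        cyto = classify_cytotoxicity(viability, line, alpha=alpha)
        details[line] = cyto
        labels[line] = cyto.set_index("species_id")["cytotoxic"].reindex(labels.index)
    if labels.isna().any().any():
        missing = labels.index[labels.isna().any(axis=1)]
        raise ValueError("species missing from some assay: " + ", ".join(map(str, missing)))
    labels = labels.astype(bool)
    return (
        ActivityLabels(labels=labels, thresholds={"radius_cm": radius_threshold_cm, "alpha": alpha}),
        details,
    )


def labels_long_csv(labels: ActivityLabels, details: dict) -> pd.DataFrame:
    """Long-format labels table with the per-assay statistic and adjusted p."""
    long = labels.to_long()
    stat, p_adj = [], []
    for _, row in long.iterrows():
        det = details.get(row["assay"])
        if det is None:
            stat.append(np.nan), p_adj.append(np.nan)
            continue
        det_row = det[det["species_id"] == row["species_id"]]
        if row["assay"] == "AM":
            stat.append(float(det_row["mean_radius_cm"].iloc[0]))
            p_adj.append(np.nan)
        else:
            stat.append(float(det_row["viability_percent"].iloc[0]))
            val = det_row["p_adj"].iloc[0]
            p_adj.append(float(val) if pd.notna(val) else np.nan)
    long["statistic"] = stat
    long["p_adj"] = p_adj
    return long
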