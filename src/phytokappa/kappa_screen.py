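"""Per-feature categorical agreement screening with Cohen's kappa.

Each binarized LC-MS feature profile is treated as one "rater" and a binary
bioactivity classification (antimicrobial, HaCaT cytotoxicity, IEC-6
cytotoxicity) as the second rater.  Agreement is quantified by Cohen's
chance-corrected kappa on the 2x2 contingency table, significance by a
two-sided Fisher exact test with Benjamini-Hochberg correction, and
features are ordered by competition (min) rank.

The combined score

    kappa_C = kappa_AM - (kappa_HaCaT + kappa_IEC6)

rewards agreement with the antimicrobial classification while penalising
agreement with either cytotoxicity classification; a feature is *selected*
as a candidate for an antimicrobial-but-non-cytotoxic compound when both
kappa_C and kappa_AM reach the "strong" tier (>= 0.68 by default).
"""

from __future__ import annotations

import functools
import logging
import warnings
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: kappa tier boundaries: strong >= 0.68, moderate in [0.35, 0.68)
STRONG_KAPPA = 0.68
MODERATE_KAPPA = 0.35


class ContingencyTable2x2(NamedTuple):
    """Counts cross-classifying feature presence against an activity label.

    ``a``: present & active, ``b``: present & inactive,
    ``c``: absent & active,  ``d``: absent & inactive.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_table(x: np.ndarray, y: np.ndarray) -> ContingencyTable2x2:
    """Cross-tabulate two equal-length binary vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return ContingencyTable2x2(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def cohen_kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa for a 2x2 contingency table.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (a+d)/n and chance agreement
    p_e = [(a+b)(a+c) + (c+d)(b+d)] / n**2.

    Returns NaN when p_e = 1 (both raters constant in the same direction),
    where agreement beyond chance is undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("contingency table is empty")
    pe_num = (a + b) * (a + c) + (c + d) * (b + d)
    if pe_num == n * n:
        return float("nan")
    po = (a + d) / n
    pe = pe_num / (n * n)
    return (po - pe) / (1 - pe)


def kappa_from_counts(a, b, c, d):
    """Vectorised Cohen's kappa over arrays of 2x2 counts (NaN where undefined).

    Uses the same floating-point expression as :func:`cohen_kappa` so scalar
    and vectorised paths agree bitwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    pe_num = (a + b) * (a + c) + (c + d) * (b + d)
    po = (a + d) / n
    pe = pe_num / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1 - pe)
    return np.where(pe_num == n * n, np.nan, kappa)


def strength_class(kappa: float) -> str:
    """Tier a kappa value: ``strong`` (>= 0.68), ``moderate`` ([0.35, 0.68)), ``low``."""
    if np.isnan(kappa):
        raise ValueError("kappa is undefined; no strength class")
    if kappa >= STRONG_KAPPA:
        return "strong"
    if kappa >= MODERATE_KAPPA:
        return "moderate"
    return "low"


def benjamini_hochberg(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR procedure.

    Returns ``(reject, p_adjusted)`` with monotone adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@functools.lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def competition_rank(values: np.ndarray) -> np.ndarray:
    """Competition (min) rank of values in descending order; NaN values get NaN rank.

    Tied values share the smallest rank of their block, so three features
    tied at the top all hold rank 1 and the next distinct value holds rank 4.
    """
    values = np.asarray(values, dtype=float)
    ranks = np.full(values.shape, np.nan)
    defined = ~np.isnan(values)
    if defined.any():
        ranks[defined] = stats.rankdata(-values[defined], method="min")
    return ranks


def screen(
    binary_matrix,
    labels: pd.Series,
    assay: str = "AM",
    alpha: float = 0.05,
    compute_p: bool = True,
) -> pd.DataFrame:
    """Kappa-screen every feature profile against one activity classification.

    Parameters
    ----------
    binary_matrix
        A :class:`~phytokappa.feature_table.BinaryPeakMatrix` or a boolean
        DataFrame (species x features).
    labels
        Boolean Series indexed by species id (True = active).
    assay
        Name recorded in the output (``AM``, ``HaCaT``, ``IEC-6``).
    alpha
        FDR level for the Benjamini-Hochberg flag.
    compute_p
        When False, skip Fisher tests (p_value/p_adj/bh_significant are NaN);
        kappa and ranks are unaffected.

    Returns
    -------
    DataFrame with one row per feature: ``feature_id, assay, a, b, c, d,
    kappa, p_value, p_adj, bh_significant, rank, strength``.  Undefined
    kappas (constant combined margins) are flagged with NaN and excluded
    from ranking.
    """
    presence = getattr(binary_matrix, "presence", binary_matrix)
    missing = set(presence.index) ^ set(labels.index)
    if missing:
        raise ValueError(
            "species sets of matrix and labels differ: " + ", ".join(sorted(map(str, missing)))
        )
    labels = labels.reindex(presence.index).astype(bool)
    X = presence.to_numpy(dtype=bool)
    L = labels.to_numpy()
    n = X.shape[0]
    a = (X & L[:, None]).sum(axis=0)
    b = X.sum(axis=0) - a
    c = int(L.sum()) - a
    d = n - a - b - c
    kappa = kappa_from_counts(a, b, c, d)
    ranks = competition_rank(kappa)

    if compute_p:
        p = np.array([_fisher_p(int(ai), int(bi), int(ci), int(di))
                      for ai, bi, ci, di in zip(a, b, c, d)])
        reject, p_adj = benjamini_hochberg(p, alpha=alpha)
    else:
        p = np.full(len(a), np.nan)
        p_adj = np.full(len(a), np.nan)
        reject = np.zeros(len(a), dtype=bool)

    strength = [strength_class(k) if not np.isnan(k) else "undefined" for k in kappa]
    return pd.DataFrame(
        {
            "feature_id": presence.columns,
            "assay": assay,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "kappa": kappa,
            "p_value": p,
            "p_adj": p_adj,
            "bh_significant": reject,
            "rank": ranks,
            "strength": strength,
        }
    )


def combined_score(
    records_am: pd.DataFrame,
    records_hacat: pd.DataFrame,
    records_iec6: pd.DataFrame,
    strong: float = STRONG_KAPPA,
) -> pd.DataFrame:
    """Combine the three per-assay screens into the candidate table.

    kappa_combined = kappa_am - (kappa_hacat + kappa_iec6); a feature is
    *selected* iff kappa_combined >= strong AND kappa_am >= strong.
    Features missing from any assay screen are excluded with a warning.
    Output is sorted by ascending combined rank, ties broken by feature id.
    """
    parts = {}
    for name, rec in (("am", records_am), ("hacat", records_hacat), ("iec6", records_iec6)):
        parts[name] = rec.set_index("feature_id")[["kappa", "rank"]].rename(
            columns={"kappa": f"kappa_{name}", "rank": f"rank_{name}"}
        )
    common = parts["am"].index
    for name in ("hacat", "iec6"):
        common = common.intersection(parts[name].index)
    dropped = set(parts["am"].index) | set(parts["hacat"].index) | set(parts["iec6"].index)
    dropped -= set(common)
    if dropped:
        warnings.warn(
            f"{len(dropped)} feature(s) missing from at least one assay screen; excluded",
            stacklevel=2,
        )
    merged = pd.concat([parts[name].loc[common] for name in ("am", "hacat", "iec6")], axis=1)
    merged["kappa_combined"] = merged["kappa_am"] - (merged["kappa_hacat"] + merged["kappa_iec6"])
    merged["rank_c"] = competition_rank(merged["kappa_combined"].to_numpy())
    merged["selected"] = (merged["kappa_combined"] >= strong) & (merged["kappa_am"] >= strong)
    merged = merged.reset_index().rename(columns={"index": "feature_id"})
    merged = merged.sort_values(
        ["rank_c", "feature_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    cols = [
        "feature_id", "kappa_am", "kappa_hacat", "kappa_iec6",
        "kappa_combined", "rank_c", "rank_am", "rank_hacat", "rank_iec6", "selected",
    ]
    return merged[cols]


def compound_ttest(
    peak_table,
    annotation: Mapping[str, str],
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed unpaired t-test of compound intensity, active vs inactive species.

    Features mapping to the same identified compound have their intensities
    summed per species.  The pooled-variance (equal-variance) t-test is used.
    A compound whose intensities are constant in both classes has an
    undefined statistic and is flagged, never called significant.
    """
    intensity = peak_table.intensity
    labels = labels.reindex(intensity.index).astype(bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 species in each activity class")
    ann = pd.Series(dict(annotation))
    unknown = set(ann.index) - set(intensity.columns)
    if unknown:
        raise ValueError("annotation references unknown features: " + ", ".join(sorted(unknown)))
    rows = []
    for compound, feats in ann.groupby(ann).groups.items():
        values = intensity[list(feats)].sum(axis=1)
        act = values[labels].to_numpy()
        inact = values[~labels].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(act, inact, equal_var=True)
        defined = np.isfinite(t)
        rows.append(
            {
                "compound": compound,
                "n_features": len(feats),
                "n_active": act.size,
                "n_inactive": inact.size,
                "t": float(t) if defined else np.nan,
                "p_value": float(p) if defined else np.nan,
                "defined": bool(defined),
                "significant": bool(defined and p < alpha),
            }
        )
    return pd.DataFrame(rows).sort_values("compound").reset_index(drop=True)
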