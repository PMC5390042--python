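"""Exhaustive Boolean AND/OR pairwise combination screen.

Every unordered pair of binarized feature profiles is combined elementwise
(AND as an additivity/synergy proxy, OR as a functional-redundancy proxy)
and the combined profile's Cohen's kappa against the activity labels is
computed.  A pair *outperforms* when its kappa strictly exceeds the best
individual feature's kappa.

At full study scale (~48k features, > 10^9 pairs) per-pair vector
allocation is infeasible, so the kernel works blockwise on Gram matrices:
for a block of features, one matrix product against all features yields the
pairwise intersection counts overall and within the active species, from
which all four contingency cells follow in closed form for both operators.
Evaluation streams block by block with bounded memory; only pairs at or
above a report threshold are ever materialised.

Note on interpretation: maximising kappa over ~F^2/2 pairs inflates the
best value relative to the best of F individual features even under the
null (a selection-maximum effect); summaries carry an explicit annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .kappa_screen import STRONG_KAPPA, kappa_from_counts

logger = logging.getLogger(__name__)

OPERATORS = ("AND", "OR")

SELECTION_MAX_NOTE = (
    "best-pair kappa is a maximum over all pairs and exceeds the best "
    "individual kappa in expectation even for label-independent features; "
    "compare pair counts, not maxima, across screens"
)


def combine_profiles(x, y, operator: str) -> np.ndarray:
    """Elementwise Boolean combination of two binary profiles."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if operator == "AND":
        return x & y
    if operator == "OR":
        return x | y
    raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")


@dataclass
class PairScreenSummary:
    """Whole-screen tallies; counts always cover all C(F,2) pairs."""

    operator: str
    n_pairs_evaluated: int
    n_undefined: int
    n_strong: int
    n_outperforming: int
    best_pair_kappa: float
    best_pair: tuple | None
    best_individual_kappa: float
    strong_threshold: float
    report_threshold: float
    note: str = SELECTION_MAX_NOTE

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["best_pair"] = list(self.best_pair) if self.best_pair else None
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _individual_kappas(X: np.ndarray, L: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    a = X[:, L].sum(axis=1).astype(np.float64)
    tot = X.sum(axis=1).astype(np.float64)
    k_act = float(L.sum())
    b = tot - a
    c = k_act - a
    d = n - tot - c
    return kappa_from_counts(a, b, c, d)


def pairwise_screen(
    binary_matrix,
    labels: pd.Series,
    operator: str,
    strong: float = STRONG_KAPPA,
    report_threshold: float = STRONG_KAPPA,
    block_size: int = 512,
) -> tuple[pd.DataFrame, PairScreenSummary]:
    """Screen all unordered feature pairs under one Boolean operator.

    Parameters
    ----------
    binary_matrix
        BinaryPeakMatrix or boolean DataFrame (species x features), >= 2 features.
    labels
        Boolean activity Series indexed by species id.
    operator
        ``"AND"`` or ``"OR"``.
    strong, report_threshold
        Tier threshold for the summary tally and the materialisation cut-off
        for records (summary counts always cover every pair).
    block_size
        Feature rows per Gram-matrix block (memory/speed trade-off).

    Returns
    -------
    (records, summary): records holds one row per pair with kappa >=
    report_threshold — ``feature_i, feature_j, operator, kappa,
    outperforming`` with i < j in column order — sorted by descending kappa.
    Pairs whose combined profile is constant have undefined kappa: they count
    as evaluated but never as strong or outperforming.
    """
    if operator not in OPERATORS:
        raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")
    presence = getattr(binary_matrix, "presence", binary_matrix)
    missing = set(presence.index) ^ set(labels.index)
    if missing:
        raise ValueError(
            "species sets of matrix and labels differ: " + ", ".join(sorted(map(str, missing)))
        )
    labels = labels.reindex(presence.index).astype(bool)
    feature_ids = list(presence.columns)
    F = len(feature_ids)
    if F < 2:
        raise ValueError("pairwise screen needs >= 2 features")
    X = presence.to_numpy(dtype=bool).T  # features x species
    L = labels.to_numpy()
    n = X.shape[1]
    k_act = float(L.sum())

    indiv = _individual_kappas(X, L)
    best_individual = float(np.nanmax(indiv)) if np.any(~np.isnan(indiv)) else float("nan")

    Xf = np.ascontiguousarray(X, dtype=np.float64)
    XLf = np.ascontiguousarray(X[:, L], dtype=np.float64)
    row_tot = Xf.sum(axis=1)
    row_act = XLf.sum(axis=1)

    n_undefined = 0
    n_strong = 0
    n_outperforming = 0
    best_kappa = -np.inf
    best_pair = None
    rec_i: list[np.ndarray] = []
    rec_j: list[np.ndarray] = []
    rec_k: list[np.ndarray] = []

    for start in range(0, F, block_size):
        stop = min(start + block_size, F)
        inter = Xf[start:stop] @ Xf.T          # |x ^ y|
        inter_act = XLf[start:stop] @ XLf.T    # |x ^ y ^ L|
        if operator == "AND":
            tot = inter
            a = inter_act
        else:
            tot = row_tot[start:stop, None] + row_tot[None, :] - inter
            a = row_act[start:stop, None] + row_act[None, :] - inter_act
        b = tot - a
        c = k_act - a
        d = n - tot - c
        kappa = kappa_from_counts(a, b, c, d)
        # keep strictly-upper-triangle pairs only (j > global i)
        cols = np.arange(F)[None, :]
        rows_global = np.arange(start, stop)[:, None]
        valid = cols > rows_global
        kv = np.where(valid, kappa, np.nan)
        pair_mask = valid
        undef_mask = pair_mask & np.isnan(kappa)
        n_undefined += int(undef_mask.sum())
        defined = pair_mask & ~np.isnan(kappa)
        n_strong += int((defined & (kappa >= strong)).sum())
        if not np.isnan(best_individual):
            n_outperforming += int((defined & (kappa > best_individual)).sum())
        blk_max = np.nanmax(kv) if np.any(defined) else -np.inf
        if blk_max > best_kappa:
            best_kappa = float(blk_max)
            bi, bj = np.unravel_index(np.nanargmax(kv), kv.shape)
            best_pair = (feature_ids[start + bi], feature_ids[bj])
        keep = defined & (kappa >= report_threshold)
        if keep.any():
            ii, jj = np.nonzero(keep)
            rec_i.append(ii + start)
            rec_j.append(jj)
            rec_k.append(kappa[keep])

    n_pairs = F * (F - 1) // 2
    if rec_i:
        ii = np.concatenate(rec_i)
        jj = np.concatenate(rec_j)
        kk = np.concatenate(rec_k)
        records = pd.DataFrame(
            {
                "feature_i": [feature_ids[i] for i in ii],
                "feature_j": [feature_ids[j] for j in jj],
                "operator": operator,
                "kappa": kk,
                "outperforming": (kk > best_individual)
                if not np.isnan(best_individual)
                else False,
            }
        ).sort_values(
            ["kappa", "feature_i", "feature_j"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
    else:
        records = pd.DataFrame(
            columns=["feature_i", "feature_j", "operator", "kappa", "outperforming"]
        )

    summary = PairScreenSummary(
        operator=operator,
        n_pairs_evaluated=n_pairs,
        n_undefined=n_undefined,
        n_strong=n_strong,
        n_outperforming=n_outperforming,
        best_pair_kappa=best_kappa if best_kappa > -np.inf else float("nan"),
        best_pair=best_pair,
        best_individual_kappa=best_individual,
        strong_threshold=strong,
        report_threshold=report_threshold,
    )
    return records, summary


@dataclass
class InvolvementStats:
    """How often a focus set of features participates in outperforming pairs."""

    n_records: int
    fraction_involving_focus: float
    per_feature_fraction: pd.Series


def involvement_stats(records: pd.DataFrame, focus_set) -> InvolvementStats:
    """Fraction of pair records with >= 1 endpoint in ``focus_set``.

    Also returns, for each focus feature, the fraction of records containing
    it.  With no records the fractions are undefined (NaN).
    """
    focus = set(focus_set)
    n = len(records)
    if n == 0:
        return InvolvementStats(
            n_records=0,
            fraction_involving_focus=float("nan"),
            per_feature_fraction=pd.Series({f: float("nan") for f in sorted(focus)}, dtype=float),
        )
    in_focus = records["feature_i"].isin(focus) | records["feature_j"].isin(focus)
    per_feature = {
        f: float(((records["feature_i"] == f) | (records["feature_j"] == f)).mean())
        for f in sorted(focus)
    }
    return InvolvementStats(
        n_records=n,
        fraction_involving_focus=float(in_focus.mean()),
        per_feature_fraction=pd.Series(per_feature, dtype=float),
    )


def top_pairs_heatmap_table(
    records: pd.DataFrame,
    k: int,
    individual_kappa: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Plotting-ready symmetric kappa matrix over the top-k involved features.

    Features are ranked by descending membership count in the (outperforming)
    records, ties broken by individual kappa then feature id.  Cells hold the
    pair kappa where the pair appears in ``records`` and NaN otherwise
    (including the diagonal: self-pairs are never evaluated).  The marginal
    Series carries the individual kappas of the selected features.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict = {}
    for col in ("feature_i", "feature_j"):
        for f, c in records[col].value_counts().items():
            counts[f] = counts.get(f, 0) + int(c)
    ordered = sorted(
        counts,
        key=lambda f: (-counts[f], -individual_kappa.get(f, float("-inf")), str(f)),
    )
    top = ordered[:k]
    mat = pd.DataFrame(np.nan, index=top, columns=top)
    sel = records[records["feature_i"].isin(top) & records["feature_j"].isin(top)]
    for _, row in sel.iterrows():
        mat.loc[row["feature_i"], row["feature_j"]] = row["kappa"]
        mat.loc[row["feature_j"], row["feature_i"]] = row["kappa"]
    return mat, individual_kappa.reindex(top)
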