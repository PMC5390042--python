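import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytokappa.boolean_screen import (
    combine_profiles,
    involvement_stats,
    pairwise_screen,
    top_pairs_heatmap_table,
)
from phytokappa.kappa_screen import cohen_kappa, contingency_table, screen

profiles = st.lists(st.booleans(), min_size=1, max_size=40)


class TestCombineProfiles:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(profiles)
    def test_identity_elements(self, x):
        x = np.array(x, dtype=bool)
        assert np.array_equal(combine_profiles(x, np.ones_like(x), "AND"), x)
        assert np.array_equal(combine_profiles(x, np.zeros_like(x), "OR"), x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(profiles)
    def test_idempotence(self, x):
        x = np.array(x, dtype=bool)
        assert np.array_equal(combine_profiles(x, x, "AND"), x)
        assert np.array_equal(combine_profiles(x, x, "OR"), x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(profiles, st.randoms(use_true_random=False))
    def test_commutativity(self, x, rnd):
        x = np.array(x, dtype=bool)
        y = np.array([rnd.random() < 0.5 for _ in x], dtype=bool)
        for op in ("AND", "OR"):
            assert np.array_equal(combine_profiles(x, y, op), combine_profiles(y, x, op))

    def test_length_mismatch_and_bad_operator(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_profiles([1, 0], [1], "AND")
        with pytest.raises(ValueError, match="operator"):
            combine_profiles([1, 0], [0, 1], "XOR")


def _random_dataset(n_species, n_features, seed, prevalence=0.3):
    rng = np.random.default_rng(seed)
    species = [f"s{i}" for i in range(n_species)]
    X = pd.DataFrame(
        rng.random((n_species, n_features)) < prevalence,
        index=species,
        columns=[f"f{j:03d}" for j in range(n_features)],
    )
    labels = pd.Series(rng.random(n_species) < 0.25, index=species)
    if labels.sum() == 0:
        labels.iloc[0] = True
    return X, labels


def _naive_pair_kappas(X: pd.DataFrame, labels: pd.Series, operator: str):
    """Per-pair loop oracle: explicit combination and contingency per pair."""
    cols = list(X.columns)
    L = labels.to_numpy()
    out = {}
    for i in range(len(cols)):
        xi = X[cols[i]].to_numpy()
        for j in range(i + 1, len(cols)):
            combined = combine_profiles(xi, X[cols[j]].to_numpy(), operator)
            out[(cols[i], cols[j])] = cohen_kappa(*contingency_table(combined, L))
    return out


@pytest.fixture(scope="module")
def pair_only_study():
    """Noiseless study planting only Boolean pairs (no perfect single rater)."""
    from phytokappa.bioactivity import build_activity_labels
    from phytokappa.feature_table import binarize, filter_ubiquitous
    from phytokappa.synthetic_data import SyntheticConfig, simulate_study

    cfg = SyntheticConfig(
        n_features=250, flip_noise=0.0, n_causal_single=0,
        n_synergy_pairs=1, n_redundancy_pairs=1, seed=23,
    )
    study = simulate_study(cfg)
    labels, _ = build_activity_labels(study.inhibition, study.viability)
    bmat = filter_ubiquitous(binarize(study.peak_table))
    return study, bmat, labels


class TestPairwiseScreen:
    def test_evaluates_all_unordered_pairs(self):
        X, labels = _random_dataset(20, 200, seed=0)
        _, summary = pairwise_screen(X, labels, "AND")
        assert summary.n_pairs_evaluated == 200 * 199 // 2 == 19_900

    @pytest.mark.parametrize("operator", ["AND", "OR"])
    def test_blocked_kernel_matches_naive_loop(self, operator):
        X, labels = _random_dataset(30, 60, seed=1)
        oracle = _naive_pair_kappas(X, labels, operator)
        records, summary = pairwise_screen(
            X, labels, operator, report_threshold=-2.0, block_size=17
        )
        assert len(records) + summary.n_undefined == len(oracle)
        got = {(r.feature_i, r.feature_j): r.kappa for r in records.itertuples()}
        for pair, k in oracle.items():
            if np.isnan(k):
                assert pair not in got
            else:
                assert got[pair] == k  # identical arithmetic: bitwise equal

    def test_pair_order_invariance(self):
        X, labels = _random_dataset(25, 40, seed=2)
        r1, _ = pairwise_screen(X, labels, "AND", report_threshold=-2.0)
        r2, _ = pairwise_screen(X.iloc[:, ::-1], labels, "AND", report_threshold=-2.0)
        k1 = {frozenset((r.feature_i, r.feature_j)): r.kappa for r in r1.itertuples()}
        k2 = {frozenset((r.feature_i, r.feature_j)): r.kappa for r in r2.itertuples()}
        assert k1 == k2

    def test_noiseless_planted_and_pair_tops_screen(self, pair_only_study):
        study, bmat, labels = pair_only_study
        records, summary = pairwise_screen(bmat, labels.get("AM"), "AND")
        planted = tuple(study.truth.synergy_pairs[0])
        top = records.iloc[0]
        assert {top.feature_i, top.feature_j} == set(planted)
        assert top.kappa == 1.0 > summary.best_individual_kappa
        assert top.outperforming

    def test_noiseless_planted_or_pair_tops_screen(self, pair_only_study):
        study, bmat, labels = pair_only_study
        records, summary = pairwise_screen(bmat, labels.get("AM"), "OR")
        planted = tuple(study.truth.redundancy_pairs[0])
        top = records.iloc[0]
        assert {top.feature_i, top.feature_j} == set(planted)
        assert top.kappa == 1.0 > summary.best_individual_kappa
        assert top.outperforming

    def test_constant_combined_profiles_counted_but_excluded(self):
        species = [f"s{i}" for i in range(8)]
        X = pd.DataFrame(
            {"o1": [True] * 8, "o2": [True] * 8, "z": [False] * 8},
            index=species,
        )
        labels = pd.Series([True] * 8, index=species)  # constant labels
        _, summary = pairwise_screen(X, labels, "AND", report_threshold=-2.0)
        assert summary.n_pairs_evaluated == 3
        # o1&o2 is constant-present like the labels: p_e = 1, kappa undefined
        assert summary.n_undefined == 1
        assert summary.n_strong == 0
        assert summary.n_outperforming == 0

    def test_selection_maximum_effect_on_null_data(self):
        """Maximising over ~F^2/2 pairs beats the best individual feature even
        with label-independent features; the summary carries the caveat."""
        best_pair, best_indiv = [], []
        for seed in range(10):
            X, labels = _random_dataset(40, 80, seed=100 + seed)
            _, summary = pairwise_screen(X, labels, "OR", report_threshold=2.0)
            best_pair.append(summary.best_pair_kappa)
            best_indiv.append(summary.best_individual_kappa)
        assert np.median(best_pair) > np.median(best_indiv)
        assert "maximum" in summary.note


class TestInvolvement:
    def _records(self):
        return pd.DataFrame(
            {
                "feature_i": ["a", "a", "b"],
                "feature_j": ["b", "c", "d"],
                "operator": "AND",
                "kappa": [0.9, 0.8, 0.7],
                "outperforming": [True, True, False],
            }
        )

    def test_full_focus_set_fraction_one(self):
        stats = involvement_stats(self._records(), {"a", "b", "c", "d"})
        assert stats.fraction_involving_focus == 1.0

    def test_empty_focus_set_fraction_zero(self):
        stats = involvement_stats(self._records(), set())
        assert stats.fraction_involving_focus == 0.0

    def test_no_records_fraction_undefined(self):
        empty = self._records().iloc[:0]
        stats = involvement_stats(empty, {"a"})
        assert np.isnan(stats.fraction_involving_focus)

    def test_per_feature_containment(self):
        stats = involvement_stats(self._records(), {"a", "d"})
        assert stats.per_feature_fraction["a"] == pytest.approx(2 / 3)
        assert stats.per_feature_fraction["d"] == pytest.approx(1 / 3)

    def test_planted_causal_feature_over_represented(self, study_noiseless,
                                                     binary_noiseless, labels_noiseless):
        records, _ = pairwise_screen(
            binary_noiseless, labels_noiseless.get("AM"), "OR", report_threshold=0.5
        )
        causal = study_noiseless.truth.causal_feature_ids[0]
        stats = involvement_stats(records, {causal})
        all_feats = set(records["feature_i"]) | set(records["feature_j"])
        background = [
            involvement_stats(records, {f}).per_feature_fraction[f] for f in sorted(all_feats)
        ]
        assert stats.per_feature_fraction[causal] > np.median(background)


class TestHeatmapTable:
    def _inputs(self):
        X, labels = _random_dataset(30, 25, seed=5)
        records, _ = pairwise_screen(X, labels, "OR", report_threshold=-2.0)
        indiv = screen(X, labels, compute_p=False).set_index("feature_id")["kappa"]
        return records, indiv

    def test_symmetric_with_nan_diagonal(self):
        records, indiv = self._inputs()
        mat, marginal = top_pairs_heatmap_table(records, k=10, individual_kappa=indiv)
        assert mat.shape == (10, 10)
        assert np.isnan(np.diag(mat.to_numpy())).all()
        arr = mat.to_numpy()
        assert np.array_equal(arr, arr.T, equal_nan=True)
        assert list(marginal.index) == list(mat.index)

    def test_top_k_selection_matches_sorting_oracle(self):
        records, indiv = self._inputs()
        mat, _ = top_pairs_heatmap_table(records, k=8, individual_kappa=indiv)
        counts = (
            records["feature_i"].value_counts().add(
                records["feature_j"].value_counts(), fill_value=0
            )
        )
        expected = sorted(
            counts.index, key=lambda f: (-counts[f], -indiv[f], str(f))
        )[:8]
        assert list(mat.index) == expected

    def test_k_below_two_rejected(self):
        records, indiv = self._inputs()
        with pytest.raises(ValueError):
            top_pairs_heatmap_table(records, k=1, individual_kappa=indiv)
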