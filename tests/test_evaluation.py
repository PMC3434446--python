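import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdbinder.errors import ConfigurationError, UndefinedMetricError
from pdbinder.evaluation import (ChainScores, ConfusionCounts,
                                 binding_site_radius, confusion_metrics,
                                 evaluate_chains, optimize_threshold,
                                 pooled_roc_auc, scan_cluster_radius,
                                 site_radius_stats, transfer_binding_labels)
from pdbinder.predictor import Prediction, ThresholdPolicy
from tests.conftest import make_residue


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        sens, spec, ppv, mcc = confusion_metrics(ConfusionCounts(5, 0, 5, 0))
        assert (sens, spec, ppv, mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominators_are_zero(self):
        sens, spec, ppv, mcc = confusion_metrics(ConfusionCounts(0, 0, 8, 2))
        assert ppv == 0.0 and mcc == 0.0 and sens == 0.0 and spec == 1.0

    def test_hand_evaluated_mcc(self):
        # (2*6 - 1*1) / sqrt(3*3*7*7) = 11/21
        *_, mcc = confusion_metrics(ConfusionCounts(tp=2, fp=1, tn=6, fn=1))
        assert mcc == pytest.approx(11 / 21)


def _mann_whitney_auc(records):
    """Rank-statistic oracle: AUC = U / (n_pos * n_neg), ties count 1/2."""
    pos = [s for s, l in records if l]
    neg = [s for s, l in records if not l]
    u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return u / (len(pos) * len(neg))


class TestPooledRoc:
    def test_perfect_separation(self):
        records = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
        _, auc = pooled_roc_auc(records)
        assert auc == pytest.approx(1.0)

    def test_chance_level_for_random_labels(self):
        rng = np.random.default_rng(1)
        records = [(float(rng.uniform()), bool(rng.integers(2)))
                   for _ in range(4000)]
        _, auc = pooled_roc_auc(records)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_hand_built_list_matches_rank_oracle(self):
        records = [(0.9, True), (0.7, False), (0.7, True),
                   (0.4, True), (0.3, False), (0.1, False)]
        _, auc = pooled_roc_auc(records)
        assert auc == pytest.approx(_mann_whitney_auc(records))

    @given(st.integers(0, 500))
    def test_auc_equals_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            return
        records = list(zip(scores.tolist(), labels.tolist()))
        _, auc = pooled_roc_auc(records)
        assert auc == pytest.approx(_mann_whitney_auc(records), abs=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            pooled_roc_auc([(0.5, True), (0.2, True)])


def _chain(scores, truth, chain_id="A", coords=None):
    residues = None
    if coords is not None:
        residues = [make_residue(chain_id, i + 1, "ALA", c)
                    for i, c in enumerate(coords)]
    return ChainScores(scores=np.asarray(scores, float),
                       truth=np.asarray(truth, bool),
                       aa_types=["ALA"] * len(scores),
                       residues=residues, chain_id=chain_id)


class TestOptimizeThreshold:
    def test_single_grid_value_returned(self):
        chains = [_chain([0.1, 0.9], [False, True])]
        policy, _, _ = optimize_threshold(chains, grid=[0.42])
        assert policy.general_cutoff == 0.42

    def test_all_zero_scores_lowest_cutoff_zero_mcc(self):
        chains = [_chain([0.0, 0.0, 0.0], [False, True, False])]
        policy, mcc, _ = optimize_threshold(chains, grid=[0.1, 0.5, 0.9])
        assert policy.general_cutoff == 0.1
        assert mcc == 0.0

    def test_empty_grid_raises(self):
        with pytest.raises(ConfigurationError):
            optimize_threshold([_chain([0.5], [True])], grid=[])

    def test_separable_scores_recover_boundary(self):
        chains = [_chain([0.1, 0.2, 0.6, 0.7], [False, False, True, True]),
                  _chain([0.15, 0.25, 0.55, 0.8], [False, False, True, True])]
        policy, mcc, _ = optimize_threshold(chains)
        assert mcc == pytest.approx(1.0)
        assert 0.25 < policy.general_cutoff <= 0.55

    def test_macro_mcc_invariant_under_chain_reorder(self):
        rng = np.random.default_rng(1)
        chains = [_chain(rng.uniform(size=10), rng.integers(0, 2, 10),
                         chain_id=f"C{i}") for i in range(4)]
        _, mcc_fwd, _ = optimize_threshold(chains, grid=[0.3])
        _, mcc_rev, _ = optimize_threshold(chains[::-1], grid=[0.3])
        assert mcc_fwd == pytest.approx(mcc_rev)

    def test_per_aa_mode_never_worse_than_general(self):
        # LEU needs a lower cutoff than the other types to be separable
        chains = [ChainScores(
            scores=np.array([0.05, 0.30, 0.02, 0.60, 0.90, 0.10]),
            truth=np.array([True, False, False, True, True, False]),
            aa_types=["LEU", "LEU", "LEU", "HIS", "HIS", "HIS"])]
        _, mcc_general, _ = optimize_threshold(chains)
        policy, mcc_aa, _ = optimize_threshold(chains, per_aa=True)
        assert mcc_aa >= mcc_general
        assert policy.mode == "residue_specific"
        assert policy.cutoff_for("LEU") <= policy.cutoff_for("HIS")


class TestRadiusScan:
    def _chain_preds(self, positions, raw, truth):
        preds = [Prediction(residue=make_residue("A", i + 1, "ALA", p),
                            pr=0.5, raw_positive=r, final_positive=r)
                 for i, (p, r) in enumerate(zip(positions, raw))]
        return preds, np.asarray(truth, bool)

    def test_cluster_plus_isolated_false_positives(self):
        # true positives form one ~8 A-diameter cluster; false positives are
        # isolated >20 A away, so a radius >= 8 removes them
        positions = [[0, 0, 0], [4, 0, 0], [8, 0, 0],
                     [40, 0, 0], [80, 40, 0]]
        raw = [True] * 5
        truth = [True, True, True, False, False]
        chain = self._chain_preds(positions, raw, truth)
        best, table = scan_cluster_radius([chain])
        mcc_by_radius = dict(table)
        unfiltered_calls = np.array(raw)
        from pdbinder.evaluation import confusion_from_calls
        *_, mcc_raw = confusion_metrics(
            confusion_from_calls(unfiltered_calls, np.array(truth)))
        assert best >= 4.0
        assert mcc_by_radius[best] > mcc_raw

    def test_single_radius_list(self):
        chain = self._chain_preds([[0, 0, 0], [5, 0, 0]], [True, True],
                                  [True, True])
        best, _ = scan_cluster_radius([chain], radii=[7.0])
        assert best == 7.0

    def test_no_positives_ties_break_to_smallest(self):
        chain = self._chain_preds([[0, 0, 0], [5, 0, 0]], [False, False],
                                  [True, False])
        best, _ = scan_cluster_radius([chain], radii=[3.0, 5.0, 9.0])
        assert best == 3.0


class TestSiteRadius:
    def test_single_residue_zero(self):
        assert binding_site_radius([make_residue("A", 1, "ALA", [1, 2, 3])]) == 0.0

    def test_two_residues_half_distance(self):
        pocket = [make_residue("A", 1, "ALA", [0, 0, 0]),
                  make_residue("A", 2, "ALA", [10, 0, 0])]
        assert binding_site_radius(pocket) == pytest.approx(5.0)

    def test_matches_direct_centroid_arithmetic(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 15, size=(5, 3))
        pocket = [make_residue("A", i + 1, "ALA", c)
                  for i, c in enumerate(coords)]
        centroid = coords.mean(axis=0)
        expected = max(np.linalg.norm(c - centroid) for c in coords)
        assert binding_site_radius(pocket) == pytest.approx(expected)

    def test_empty_pocket_raises(self):
        with pytest.raises(ValueError):
            binding_site_radius([])

    def test_cohort_stats(self):
        pockets = [[make_residue("A", 1, "ALA", [0, 0, 0]),
                    make_residue("A", 2, "ALA", [2 * r, 0, 0])]
                   for r in [4.0, 5.0, 6.0]]
        mean, half = site_radius_stats(pockets)
        assert mean == pytest.approx(5.0)
        assert half > 0


class TestEvaluateChains:
    def test_report_contents(self):
        chains = [_chain([0.9, 0.8, 0.1, 0.05], [True, True, False, False],
                         coords=[[0, 0, 0], [4, 0, 0], [30, 0, 0], [60, 0, 0]])]
        report = evaluate_chains(chains, ThresholdPolicy(general_cutoff=0.5,
                                                         clustering_radius=10.0))
        assert report.per_chain[0]["tp"] == 2
        assert report.macro["mcc"] == pytest.approx(1.0)
        assert report.auc == pytest.approx(1.0)


class TestLabelTransfer:
    def _chain_with_labels(self, nums, types, binding):
        out = []
        for n, t, b in zip(nums, types, binding):
            r = make_residue("H", n, t, [4.0 * n, 0, 0])
            r.is_binding = b
            out.append(r)
        return out

    def test_transfer_by_numbering(self):
        holo = self._chain_with_labels([1, 2, 3], ["ALA", "GLY", "SER"],
                                       [True, False, True])
        apo = [make_residue("P", n, t, [0, 0, 4.0 * n])
               for n, t in zip([1, 2, 3], ["ALA", "GLY", "SER"])]
        transfer_binding_labels(holo, apo)
        assert [r.is_binding for r in apo] == [True, False, True]

    def test_alignment_fallback_for_shifted_numbering(self):
        holo = self._chain_with_labels([1, 2, 3, 4],
                                       ["ALA", "GLY", "SER", "THR"],
                                       [False, True, True, False])
        # same sequence, numbering offset by 100 and one extra N-terminal
        # residue in the apo form
        apo_types = ["MET", "ALA", "GLY", "SER", "THR"]
        apo = [make_residue("P", 100 + i, t, [0, 0, 4.0 * i])
               for i, t in enumerate(apo_types)]
        transfer_binding_labels(holo, apo)
        assert [r.is_binding for r in apo] == [False, False, True, True, False]
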