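"""PMA screen tests: rarefaction, viability thresholds, dataset screening,
community summaries and rank correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutherit.datatypes import OtuTable
from gutherit.screen import (classify_otu_viability, rarefy, screen_dataset,
                             spearman_matrix, summarize_community)
from gutherit.simulate import SimTruth, simulate_paired_pma


class TestRarefy:
    def test_total_equals_depth_is_identity(self):
        v = np.array([3, 4, 3])
        assert np.array_equal(rarefy(v, 10, seed=0), v)

    def test_output_sums_to_depth(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 5000, size=50)
        v[0] += 20000
        out = rarefy(v, 10000, seed=1)
        assert out.sum() == 10000
        assert (out <= v).all()

    def test_hypergeometric_expectation(self):
        """(5,5) at depth 4: first entry averages 2.0 over many seeds."""
        vals = [rarefy(np.array([5, 5]), 4, seed=s)[0] for s in range(10000)]
        assert abs(np.mean(vals) - 2.0) < 0.05

    def test_insufficient_reads_rejected(self):
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(np.array([3, 4]), 100)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rarefy(np.array([-1, 5]), 2)

    def test_preserves_expected_relative_abundance(self):
        v = np.array([6000, 3000, 1000, 0])
        draws = np.array([rarefy(v, 1000, seed=s) for s in range(300)])
        rel = draws.mean(axis=0) / 1000
        assert np.allclose(rel, v / v.sum(), atol=0.01)


class TestClassify:
    @pytest.mark.parametrize("u,p,label", [
        (60, 5, "contaminant"),   # ~12-fold untreated excess
        (40, 10, "dead"),         # ~4-fold
        (10, 10, "live"),         # ratio 1
        (0, 0, "undetected"),
        (0, 50, "live"),          # strong PMA-only signal is live
    ])
    def test_threshold_labels(self, u, p, label):
        assert classify_otu_viability(u, p).label == label

    def test_label_ratio_consistency(self):
        """Labels respect the fold thresholds on the reported ratio."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            u, p = rng.integers(0, 500, size=2)
            call = classify_otu_viability(int(u), int(p))
            if call.label == "contaminant":
                assert call.ratio > 6
            elif call.label == "dead":
                assert 3 < call.ratio <= 6
            elif call.label == "live":
                assert call.ratio <= 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_otu_viability(-1, 3)
        with pytest.raises(ValueError):
            classify_otu_viability(1, 1, dead_fold=0.5)

    @given(u=st.integers(0, 10000), p=st.integers(0, 10000),
           contam=st.floats(6.0, 30.0))
    @settings(max_examples=200, deadline=None)
    def test_raising_contaminant_fold_is_monotone(self, u, p, contam):
        """A higher contaminant threshold never creates new contaminants."""
        base = classify_otu_viability(u, p, contam_fold=6.0)
        stricter = classify_otu_viability(u, p, contam_fold=contam)
        if base.label != "contaminant":
            assert stricter.label != "contaminant"


def _paired_tables(seed=0, n_samples=40, dead_share=0.10, dead_fold=5.0,
                   contam_fold=10.0, contam_share=0.001, depth=20000):
    """Construct paired arms with an exact planted untreated dead-read share.

    Solves the closure equation so that after renormalisation the dead OTU
    carries ``dead_share`` of the untreated reads in expectation.
    """
    rng = np.random.default_rng(seed)
    n_live = 5
    live_rel = rng.dirichlet(np.full(n_live, 20), size=n_samples)
    s, f = dead_share, dead_fold
    q_dead = s / (f - s * f + s)  # live-arm share giving untreated share s
    q_contam = contam_share / contam_fold
    scale = 1.0 - q_dead - q_contam
    rel = np.column_stack([live_rel * scale,
                           np.full(n_samples, q_dead),
                           np.full(n_samples, q_contam)])
    otus = [f"OTU{i+1}" for i in range(n_live)] + ["DEAD1", "CONTAM1"]
    counts = np.vstack([rng.multinomial(depth, rel[i])
                        for i in range(n_samples)])
    live = OtuTable(counts=pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)], columns=otus),
        arm="live")
    truth = SimTruth(h2=np.zeros(7), c2=np.zeros(7),
                     dead_folds={"DEAD1": dead_fold},
                     contam_folds={"CONTAM1": contam_fold}, seed=seed)
    pma, untr = simulate_paired_pma(live, truth, depth=depth, seed=seed + 1)
    return pma, untr


class TestScreenDataset:
    def test_all_live_data_yields_zero_fractions(self, small_sim):
        truth = SimTruth(h2=[0.3, 0.1, 0.0], c2=[0.1, 0.05, 0.0], seed=11)
        pma, untr = simulate_paired_pma(small_sim["live"], truth,
                                        depth=20000, seed=3)
        res = screen_dataset(pma, untr, depth=10000, seed=5)
        assert res.summary.fraction_dead_reads == 0.0
        assert res.summary.fraction_contaminant_reads == 0.0
        assert res.summary.n_otus_dead == 0

    def test_planted_dead_fraction_recovered(self):
        """10% planted dead reads recovered within +-2 points (5 seeds)."""
        fractions = []
        for seed in range(5):
            pma, untr = _paired_tables(seed=seed)
            res = screen_dataset(pma, untr, depth=10000, seed=seed)
            fractions.append(res.summary.fraction_dead_reads)
        assert abs(np.mean(fractions) - 0.10) < 0.02

    def test_planted_contaminant_set_exact(self):
        pma, untr = _paired_tables(seed=1, contam_share=0.005)
        res = screen_dataset(pma, untr, depth=10000, seed=1)
        modal = res.calls.groupby("otu")["label"].agg(
            lambda x: x.value_counts().idxmax())
        assert set(modal.index[modal == "contaminant"]) == {"CONTAM1"}

    def test_low_depth_sample_fails_qc(self):
        pma, untr = _paired_tables(seed=2, depth=10000)
        untr.counts.loc["s0"] = (untr.counts.loc["s0"] * 0.9).astype(int)
        res = screen_dataset(pma, untr, depth=10000, seed=0)
        assert "s0" not in res.qc_pass
        assert "s1" in res.qc_pass

    def test_per_sample_call_partition(self):
        """live + dead + contaminant calls = OTUs observed in either arm."""
        pma, untr = _paired_tables(seed=3)
        res = screen_dataset(pma, untr, depth=10000, seed=3)
        by_sample = res.calls.groupby("sample").size()
        assert (by_sample <= len(untr.otu_ids)).all()
        assert set(res.calls["label"]) <= {"live", "dead", "contaminant"}

    def test_disjoint_sample_ids_error(self, small_sim):
        live = small_sim["live"]
        other = OtuTable(counts=live.counts.rename(index=lambda s: s + "_x"))
        with pytest.raises(ValueError, match="no sample ids"):
            screen_dataset(live, other)


class TestSummarize:
    def test_identical_samples_return_composition(self):
        counts = pd.DataFrame([[50, 30, 20]] * 2, index=["a", "b"],
                              columns=["OTU1", "OTU2", "OTU3"])
        per_otu, high, _ = summarize_community(OtuTable(counts=counts))
        assert np.allclose(per_otu["mean_rel_abundance"], [0.5, 0.3, 0.2])
        assert set(high) == {"OTU1", "OTU2", "OTU3"}

    def test_single_dominant_otu(self):
        counts = pd.DataFrame([[100, 0], [200, 0]], index=["a", "b"],
                              columns=["OTU1", "OTU2"])
        _, high, _ = summarize_community(OtuTable(counts=counts))
        assert high == ["OTU1"]

    def test_six_dominant_otus_structure(self):
        """A composition mimicking 6 dominant + many rare OTUs yields
        exactly six OTUs above the 1% mean-abundance threshold."""
        rng = np.random.default_rng(0)
        dominant = np.array([0.33, 0.35, 0.08, 0.05, 0.03, 0.02])
        rare = np.full(20, (1 - dominant.sum()) / 20)  # 0.7% each
        rel = np.concatenate([dominant, rare])
        counts = np.vstack([rng.multinomial(10000, rel) for _ in range(30)])
        table = OtuTable(counts=pd.DataFrame(
            counts, index=[f"s{i}" for i in range(30)],
            columns=[f"OTU{j+1}" for j in range(26)]))
        _, high, _ = summarize_community(table, abundance_threshold=0.01)
        assert high == ["OTU1", "OTU2", "OTU3", "OTU4", "OTU5", "OTU6"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_community(OtuTable(counts=pd.DataFrame()))


class TestSpearman:
    def _table(self, cols):
        return OtuTable(counts=pd.DataFrame(
            cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))]))

    def test_monotone_transform_gives_unit_correlation(self):
        x = np.array([1, 2, 3, 5, 8])
        t = self._table({"a": x, "b": np.exp(x).astype(int)})
        m = spearman_matrix(t)
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = self._table({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert spearman_matrix(t).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        t = self._table({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3]})
        assert spearman_matrix(t).loc["a", "b"] == pytest.approx(0.6)

    def test_constant_column_reported_missing(self):
        t = self._table({"a": [1, 2, 3], "b": [5, 5, 5]})
        m = spearman_matrix(t)
        assert np.isnan(m.loc["a", "b"])
        assert m.loc["b", "b"] == 1.0

    def test_too_few_samples_rejected(self):
        t = OtuTable(counts=pd.DataFrame({"a": [1, 2], "b": [2, 1]},
                                         index=["s0", "s1"]))
        with pytest.raises(ValueError):
            spearman_matrix(t)
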