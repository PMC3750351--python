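"""All-pairs correlation, q-values and the three-criterion link filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from comirnet.coexpression import decompose
from comirnet.io_formats import ValidationError
from comirnet.module_trait import TraitAssociatedModules
from comirnet.pair_integration import (PairCorrelationTable,
                                       all_pairs_correlation, attach_qvalues,
                                       confirmed_subset,
                                       filter_negative_pairs, integrate,
                                       qvalues)

from conftest import make_expression


def qvalues_oracle(p, m=None, pi0=1.0):
    """Independent re-implementation: direct min over the tail definition."""
    p = np.asarray(p, dtype=float)
    m_eff = m if m is not None else len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    q = np.empty(len(p))
    for i in range(len(p)):
        tail = [pi0 * m_eff * p[j] / ranks[j] for j in range(len(p))
                if p[j] >= p[i]]
        q[i] = min(1.0, min(tail))
    return q


class TestAllPairs:
    def test_study_scale_test_count(self):
        # m is the full grid implied by the probe lists even when the
        # correlation pass runs on a subset
        rng = np.random.default_rng(0)
        mi = make_expression(rng.standard_normal((675, 5)),
                             probes=[f"mi{i}" for i in range(675)])
        mr = make_expression(rng.standard_normal((11191, 5)),
                             probes=[f"g{i}" for i in range(11191)])
        table = all_pairs_correlation(mi, mr,
                                      mirna_subset=[f"mi{i}" for i in range(3)],
                                      mrna_subset=[f"g{i}" for i in range(3)])
        assert table.m_total == 7_553_925
        assert len(table.records) == 9

    def test_toy_matrices_match_per_pair_oracle(self, rng):
        mi = make_expression(rng.standard_normal((2, 8)),
                             probes=["mi0", "mi1"])
        mr = make_expression(rng.standard_normal((3, 8)))
        table = all_pairs_correlation(mi, mr)
        assert len(table.records) == 6
        for rec in table.records.itertuples(index=False):
            r_ref, p_ref = stats.pearsonr(mi.data.loc[rec.miRNA],
                                          mr.data.loc[rec.mRNA])
            assert rec.r == pytest.approx(r_ref, abs=1e-12)
            assert rec.p == pytest.approx(p_ref, abs=1e-10)

    def test_negated_profile_gives_minus_one(self, rng):
        x = rng.standard_normal(10)
        mi = make_expression([x], probes=["mi0"])
        mr = make_expression([-x, rng.standard_normal(10)])
        table = all_pairs_correlation(mi, mr)
        rec = table.records.set_index("mRNA")
        assert rec.loc["g0", "r"] == pytest.approx(-1.0)

    def test_misaligned_samples_rejected(self, rng):
        mi = make_expression(rng.standard_normal((2, 5)))
        mr = make_expression(rng.standard_normal((2, 5)),
                             samples=[f"x{j}" for j in range(5)])
        with pytest.raises(ValidationError, match="aligned"):
            all_pairs_correlation(mi, mr)


class TestQvalues:
    def test_bh_hand_example(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(qvalues([1.0] * 5, method="bh"), 1.0)

    def test_storey_with_pi0_one_equals_bh(self, rng):
        for _ in range(10):
            p = rng.random(200)
            np.testing.assert_allclose(qvalues(p, "storey", pi0=1.0),
                                       qvalues(p, "bh"), atol=1e-15)

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            p = rng.random(60)
            np.testing.assert_allclose(qvalues(p, "bh"),
                                       qvalues_oracle(p), atol=1e-12)
            pi0 = float(np.clip(rng.random(), 0.2, 1.0))
            np.testing.assert_allclose(
                qvalues(p, "storey", pi0=pi0),
                qvalues_oracle(p, pi0=pi0), atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_q_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(100)
        q = qvalues(p, "storey")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            qvalues([0.5, 1.5])

    def test_external_m_is_conservative(self, rng):
        p = rng.random(50) * 1e-3
        q_local = qvalues(p, "bh")
        q_global = qvalues(p, "bh", m=1000)
        assert (q_global >= q_local - 1e-15).all()


class TestFilterNegativePairs:
    def _table(self, r, p):
        rec = pd.DataFrame({"miRNA": [f"mi{i}" for i in range(len(r))],
                            "mRNA": [f"g{i}" for i in range(len(r))],
                            "r": r, "p": p, "n": 50})
        return attach_qvalues(PairCorrelationTable(rec, len(r)), "bh")

    def test_fdr_zero_keeps_nothing(self):
        t = self._table([-0.9, -0.5], [1e-8, 1e-3])
        assert len(filter_negative_pairs(t, fdr=0.0)) == 0

    def test_positive_pairs_never_retained(self):
        t = self._table([0.9, -0.9], [1e-12, 1e-12])
        kept = filter_negative_pairs(t, fdr=0.5)
        assert list(kept.records["r"] < 0) == [True]

    def test_implied_p_cutoff_reported(self):
        t = self._table([-0.9, -0.7, -0.1], [1e-8, 1e-4, 0.8])
        kept = filter_negative_pairs(t, fdr=0.1)
        assert kept.implied_p_cutoff == pytest.approx(
            kept.records["p"].max())

    def test_partition_of_significant_pairs_by_sign(self, rng):
        r = rng.uniform(-1, 1, 300)
        p = rng.random(300) ** 3
        rec = pd.DataFrame({"miRNA": "mi", "mRNA": [f"g{i}" for i in range(300)],
                            "r": r, "p": p, "n": 50})
        t = attach_qvalues(PairCorrelationTable(rec, 300), "bh")
        sig = t.records[t.records["q"] <= 0.1]
        pos = sig[sig["r"] > 0]
        neg = sig[sig["r"] < 0]
        assert len(pos) + len(neg) == len(sig)
        assert set(pos.index).isdisjoint(set(neg.index))

    def test_planted_regulator_pairs_survive_fdr(self, default_dataset,
                                                 pipeline_result):
        planted = default_dataset.truth.edges_as_set()
        kept = set(zip(pipeline_result.negative_pairs.records["miRNA"],
                       pipeline_result.negative_pairs.records["mRNA"]))
        retained = len(planted & kept) / len(planted)
        assert retained >= 0.9


class TestIntegrate:
    def _fixture(self, rng):
        f = rng.standard_normal(30)
        mat = make_expression([f + 0.1 * rng.standard_normal(30)
                               for _ in range(4)] +
                              [rng.standard_normal(30) for _ in range(2)],
                              probes=["g0", "g1", "g2", "g3", "g4", "g5"])
        labels = pd.Series(["blue"] * 4 + ["grey"] * 2, index=mat.data.index)
        decomp = decompose(mat, labels, min_module_size=2)
        cells = pd.DataFrame([{"module": "blue", "trait": "t", "r": 0.4,
                               "p": 0.001, "n": 30}])
        trait_mods = TraitAssociatedModules(0.05, cells, cells)
        rec = pd.DataFrame([
            {"miRNA": "mi0", "mRNA": "g0", "r": -0.8, "p": 1e-9,
             "q": 1e-6, "n": 30},
            {"miRNA": "mi0", "mRNA": "g4", "r": -0.7, "p": 1e-7,
             "q": 1e-5, "n": 30},
        ])
        neg = PairCorrelationTable(rec, 12)
        preds = pd.DataFrame([{"miRNA": "mi0", "target": "g0",
                               "site_types": "8mer", "best_mfe": -30.0,
                               "seed_hit": True, "duplex_hit": True,
                               "both": True}])
        return decomp, trait_mods, neg, preds

    def test_planted_edge_emitted_with_all_flags(self, rng):
        decomp, trait_mods, neg, preds = self._fixture(rng)
        probe, family = integrate(neg, decomp, trait_mods, preds,
                                  {"mi0": "famA"})
        assert list(probe["mRNA_probe"]) == ["g0"]
        row = probe.iloc[0]
        assert row["miRNA_family"] == "famA"
        assert row["module_hit"] and row["negative_fdr_hit"]
        assert row["predicted_seed"] and row["predicted_duplex"]
        assert len(confirmed_subset(probe)) == 1

    def test_grey_gene_excluded(self, rng):
        decomp, trait_mods, neg, preds = self._fixture(rng)
        probe, _ = integrate(neg, decomp, trait_mods, preds, {})
        assert "g4" not in set(probe["mRNA_probe"])

    def test_unknown_probe_rejected(self, rng):
        decomp, trait_mods, neg, preds = self._fixture(rng)
        neg.records.loc[0, "mRNA"] = "unknown_probe"
        with pytest.raises(ValidationError, match="unknown_probe"):
            integrate(neg, decomp, trait_mods, preds, {})

    def test_family_row_carries_most_negative_pair(self, rng):
        decomp, trait_mods, neg, preds = self._fixture(rng)
        extra = pd.DataFrame([{"miRNA": "mi1", "mRNA": "g0", "r": -0.9,
                               "p": 1e-12, "q": 1e-9, "n": 30}])
        neg = PairCorrelationTable(
            pd.concat([neg.records, extra], ignore_index=True), 12)
        fam = {"mi0": "famA", "mi1": "famA"}
        probe, family = integrate(neg, decomp, trait_mods, preds, fam)
        assert len(probe) == 2 and len(family) == 1
        assert family.iloc[0]["r"] == pytest.approx(-0.9)
        assert family.iloc[0]["predicted_seed"]  # any member's evidence


class TestEndToEndRecovery:
    def test_confirmed_edges_recover_planted_truth(self, default_dataset,
                                                   pipeline_result):
        planted = default_dataset.truth.edges_as_set()
        conf = set(zip(pipeline_result.edges_confirmed["miRNA_probe"],
                       pipeline_result.edges_confirmed["mRNA_probe"]))
        recall = len(conf & planted) / len(planted)
        precision = len(conf & planted) / max(len(conf), 1)
        assert recall >= 0.7 and precision >= 0.7
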