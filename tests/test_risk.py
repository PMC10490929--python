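"""Mann-Whitney / Fisher risk association, shared-pathway counting and the
gene-name randomization control."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from vascrisk.risk import (
    RuleError,
    count_shared_pathways,
    fisher_positive_enrichment,
    mann_whitney_risk,
    null_band,
    randomize_query,
    risk_association,
)
from vascrisk.similarity import SimilarityRecord

from conftest import make_contrast
from oracles import fisher_greater_p, mw_exact_p, mw_normal_p


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney_risk([0.9, 0.8, 0.7], [0.1, 0.2])
        assert u == 6
        assert p == pytest.approx(0.1)

    def test_identical_multisets_not_significant(self):
        u, p = mann_whitney_risk([0.1, 0.2, 0.3], [0.3, 0.1, 0.2])
        assert p >= 0.5

    def test_nonrisk_all_greater(self):
        _, p = mann_whitney_risk([0.1, 0.2], [0.5, 0.6, 0.7])
        assert p > 0.5

    def test_empty_group_undefined(self):
        assert mann_whitney_risk([], [0.1]) is None
        assert mann_whitney_risk([0.1], []) is None

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (3, 7), (5, 5)]:
            for _ in range(20):
                x = list(rng.normal(size=n1))
                y = list(rng.normal(size=n2))
                _, p = mann_whitney_risk(x, y)
                assert p == pytest.approx(mw_exact_p(x, y), abs=1e-12)

    def test_asymptotic_matches_normal_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = list(rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=15))
            y = list(rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=18))
            _, p = mann_whitney_risk(x, y)
            assert p == pytest.approx(mw_normal_p(x, y), abs=1e-6)

    def test_monotonicity_in_added_risk_record(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = list(rng.normal(size=4))
            y = list(rng.normal(size=5))
            _, p_before = mann_whitney_risk(x, y)
            _, p_after = mann_whitney_risk(x + [max(x + y) + 1.0], y)
            assert p_after <= p_before + 1e-12


class TestFisher:
    def test_worked_example(self):
        odds, p = fisher_positive_enrichment([0.5, 0.6, 0.7], [0.4, -0.1, -0.2, -0.3])
        # table a=3, b=0, c=1, d=3
        assert math.isinf(odds)
        assert p == pytest.approx(4 / 35)

    def test_independence_case(self):
        odds, p = fisher_positive_enrichment([0.5, 0.5, -0.5, -0.5], [0.5, 0.5, -0.5, -0.5])
        assert odds == pytest.approx(1.0)
        assert p > 0.5

    def test_diagonal_table_boundary(self):
        # a=2, b=0, c=0, d=3 -> OR infinite, p = 1/C(5,2)
        odds, p = fisher_positive_enrichment([0.9, 0.8], [-0.1, -0.2, -0.3])
        assert math.isinf(odds)
        assert p == pytest.approx(1 / math.comb(5, 2))

    def test_matches_hypergeometric_oracle_all_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b + c + d == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            x = [1.0] * a + [-1.0] * b
            y = [1.0] * c + [-1.0] * d
            _, p = fisher_positive_enrichment(x, y)
            assert p == pytest.approx(fisher_greater_p(a, b, c, d), abs=1e-12)


def _records(query, pathway, rhos, ref_ids, cell_type="SMC"):
    return [
        SimilarityRecord(query, rid, pathway, cell_type, rho, 10)
        for rid, rho in zip(ref_ids, rhos)
    ]


class TestRiskAssociation:
    def test_grouping_and_shared_call(self):
        refs = [f"R{i}" for i in range(8)]
        labels = {r: i < 4 for i, r in enumerate(refs)}
        recs = _records("Q@1", "PW1", [0.9, 0.8, 0.85, 0.7, -0.5, -0.6, -0.7, -0.4], refs)
        recs += _records("Q@1", "PW2", [0.1, -0.2, 0.05, 0.0, 0.15, -0.1, 0.0, 0.2], refs)
        results = risk_association(recs, labels, alpha=0.05)
        by_pw = {r.pathway_id: r for r in results}
        assert by_pw["PW1"].shared and by_pw["PW1"].p_mw < 0.05
        assert not by_pw["PW2"].shared
        assert by_pw["PW1"].n_risk == 4 and by_pw["PW1"].n_nonrisk == 4

    def test_undefined_rho_and_self_excluded(self):
        refs = ["Q", "R1", "R2", "R3"]
        labels = {r: r in ("Q", "R1") for r in refs}
        rhos = [0.99, 0.9, None, -0.5]
        recs = _records("Q@1", "PW1", rhos, refs)
        results = risk_association(recs, labels)
        res = results[0]
        assert res.n_risk == 1  # Q excluded as self, R2 undefined
        assert res.n_nonrisk == 1

    def test_empty_group_marked_undefined_not_raised(self):
        refs = ["R1", "R2"]
        labels = {"R1": True, "R2": True}
        results = risk_association(_records("Q@1", "PW1", [0.5, 0.4], refs), labels)
        assert math.isnan(results[0].p_mw)
        assert not results[0].shared

    def test_count_shared_and_rules(self):
        refs = [f"R{i}" for i in range(8)]
        labels = {r: i < 4 for i, r in enumerate(refs)}
        recs = []
        for pw, sep in [("PW1", 1.0), ("PW2", 0.9), ("PW3", 0.0)]:
            rhos = [sep - 0.01 * i for i in range(4)] + [-sep + 0.01 * i for i in range(4)]
            recs += _records("Q@1", pw, rhos, refs)
        results = risk_association(recs, labels, alpha=0.05)
        n = count_shared_pathways(results, "Q@1", "SMC", alpha=0.05)
        assert n == 2
        with pytest.raises(RuleError):
            count_shared_pathways(results, "Q@1", "SMC", decision_rule="bogus")

    def test_bh_correction_is_more_conservative(self):
        refs = [f"R{i}" for i in range(8)]
        labels = {r: i < 4 for i, r in enumerate(refs)}
        recs = []
        for k in range(6):
            rhos = list(np.linspace(0.9, 0.5, 4)) + list(np.linspace(0.45, 0.1, 4))
            recs += _records("Q@1", f"PW{k}", rhos, refs)
        plain = risk_association(recs, labels, alpha=0.05)
        corrected = risk_association(recs, labels, alpha=0.05, correction="bh")
        assert sum(r.shared for r in corrected) <= sum(r.shared for r in plain)


class TestRandomizeQuery:
    def test_statistics_multiset_preserved(self):
        rng = np.random.default_rng(6)
        q = make_contrast([f"G{i}" for i in range(50)], rng.normal(size=50),
                          p_value=rng.uniform(size=50))
        r = randomize_query(q, seed=1)
        assert sorted(r.data["log_fc"]) == sorted(q.data["log_fc"])
        assert sorted(r.data["gene_id"]) == sorted(q.data["gene_id"])
        assert not r.data["gene_id"].equals(q.data["gene_id"])

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        q = make_contrast([f"G{i}" for i in range(30)], rng.normal(size=30))
        a = randomize_query(q, seed=9)
        b = randomize_query(q, seed=9)
        assert a.data["gene_id"].equals(b.data["gene_id"])
        c = randomize_query(q, seed=10)
        assert not a.data["gene_id"].equals(c.data["gene_id"])


def test_null_band_is_central_binomial_interval():
    lo, hi = null_band(100, 0.05)
    assert 0 <= lo <= 5 <= hi <= 15
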