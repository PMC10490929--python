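"""Gene filtering and pathway-level Spearman similarity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vascrisk.data import CompoundRecord, Database, ValidationError
from vascrisk.similarity import (
    SimilarityRecord,
    _spearman,
    filter_genes,
    pathway_spearman,
    read_similarity,
    similarity_matrix,
    write_similarity,
)

from conftest import make_contrast
from oracles import brute_spearman

GENES5 = ["G1", "G2", "G3", "G4", "G5"]


class TestFilterGenes:
    def test_either_contrast_rule(self):
        q = make_contrast(GENES5, [1] * 5, p_value=[0.01, 0.2, 0.9, 0.04, 0.06])
        r = make_contrast(GENES5, [1] * 5, p_value=[0.5, 0.03, 0.2, 0.9, 0.04])
        assert filter_genes(q, r, set(GENES5)) == ["G1", "G2", "G4", "G5"]

    def test_nothing_passes(self):
        q = make_contrast(GENES5, [1] * 5, p_value=[0.9] * 5)
        r = make_contrast(GENES5, [1] * 5, p_value=[0.5] * 5)
        assert filter_genes(q, r, set(GENES5)) == []

    def test_gene_absent_from_reference_excluded(self):
        q = make_contrast(GENES5, [1] * 5, p_value=[0.001] * 5)
        r = make_contrast(GENES5[:4], [1] * 4, p_value=[0.001] * 4)
        assert filter_genes(q, r, set(GENES5)) == GENES5[:4]


class TestPathwaySpearman:
    def test_worked_example(self):
        q = make_contrast(["G1", "G2", "G3", "G4"], [1.0, 0.5, -0.2, -1.0])
        r = make_contrast(["G1", "G2", "G3", "G4"], [0.8, 0.1, 0.3, -0.9])
        rec = pathway_spearman(q, r, {"G1", "G2", "G3", "G4"}, min_genes=4)
        assert rec.n_genes == 4
        assert rec.rho == pytest.approx(0.8)

    def test_self_similarity_and_negation(self):
        lfc = [1.0, 0.5, -0.2, -1.0, 2.0]
        q = make_contrast(GENES5, lfc)
        assert pathway_spearman(q, q, set(GENES5)).rho == pytest.approx(1.0)
        neg = make_contrast(GENES5, [-x for x in lfc])
        assert pathway_spearman(q, neg, set(GENES5)).rho == pytest.approx(-1.0)

    def test_undefined_below_min_genes(self):
        q = make_contrast(GENES5[:4], [1, 2, 3, 4])
        rec = pathway_spearman(q, q, set(GENES5[:4]), min_genes=5)
        assert rec.rho is None and rec.n_genes == 4

    def test_zero_rank_variance_undefined(self):
        q = make_contrast(GENES5, [1, 1, 1, 1, 1])
        r = make_contrast(GENES5, [1, 2, 3, 4, 5])
        assert pathway_spearman(q, r, set(GENES5)).rho is None

    def test_min_genes_floor(self):
        q = make_contrast(GENES5, [1, 2, 3, 4, 5])
        with pytest.raises(ValidationError, match="min_genes"):
            pathway_spearman(q, q, set(GENES5), min_genes=2)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15)
        genes = [f"G{i}" for i in range(n)]
        q = make_contrast(genes, rng.normal(size=n), p_value=rng.uniform(size=n))
        r = make_contrast(genes, rng.normal(size=n), p_value=rng.uniform(size=n))
        ab = pathway_spearman(q, r, set(genes))
        ba = pathway_spearman(r, q, set(genes))
        assert ab.n_genes == ba.n_genes
        if ab.rho is None:
            assert ba.rho is None
        else:
            assert ab.rho == pytest.approx(ba.rho)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        genes = [f"G{i}" for i in range(n)]
        lfc = rng.normal(size=n)
        q = make_contrast(genes, lfc)
        r = make_contrast(genes, rng.normal(size=n))
        base = pathway_spearman(q, r, set(genes)).rho
        warped = make_contrast(genes, np.exp(lfc) + lfc**3)  # strictly increasing
        assert pathway_spearman(warped, r, set(genes)).rho == pytest.approx(base)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(3, 30))
            x = rng.choice(np.round(rng.normal(size=n), 1), size=n)  # ties likely
            y = rng.choice(np.round(rng.normal(size=n), 1), size=n)
            ours = _spearman(x, y)
            ref = brute_spearman(x, y)
            if ours is None or ref is None:
                assert ours is None and ref is None
            else:
                assert ours == pytest.approx(ref, abs=1e-12)


def _toy_database(n_refs: int, n_genes: int, rng):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    compounds, contrasts = [], {}
    for i in range(n_refs):
        cid = f"R{i}"
        compounds.append(CompoundRecord(cid, cid, "k", True, i == 0, {}, (1e-6,)))
        for ct in ("EC", "SMC"):
            contrast = make_contrast(
                genes, rng.normal(size=n_genes), p_value=rng.uniform(0, 0.04, size=n_genes),
                treatment=f"{cid}@1e-06", cell_type=ct,
            )
            contrasts[(f"{cid}@1e-06", ct)] = contrast
    return Database(compounds=compounds, contrasts=contrasts), genes


class TestSimilarityMatrix:
    def test_cartesian_cardinality(self):
        rng = np.random.default_rng(1)
        db, genes = _toy_database(3, 40, rng)
        from vascrisk.data import Pathway, PathwayCollection

        pathways = PathwayCollection(
            Pathway(f"PW{k}", "d", frozenset(genes[10 * k:10 * (k + 1)])) for k in range(4)
        )
        queries = [
            make_contrast(genes, rng.normal(size=40), p_value=rng.uniform(0, 0.04, size=40),
                          treatment=f"Q{j}@1e-06")
            for j in range(2)
        ]
        records = similarity_matrix(queries, db, pathways, "SMC")
        assert len(records) == 2 * 3 * 4

    def test_query_as_its_own_reference(self):
        rng = np.random.default_rng(2)
        db, genes = _toy_database(2, 30, rng)
        from vascrisk.data import Pathway, PathwayCollection

        pathways = PathwayCollection([Pathway("PW0", "d", frozenset(genes[:10]))])
        query = db.contrasts[("R0@1e-06", "SMC")]
        records = similarity_matrix([query], db, pathways, "SMC")
        self_rec = next(r for r in records if r.reference_id == "R0")
        assert self_rec.rho == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        rng = np.random.default_rng(3)
        db, genes = _toy_database(2, 30, rng)
        from vascrisk.data import Pathway, PathwayCollection

        pathways = PathwayCollection([Pathway("PW0", "d", frozenset(genes[:10]))])
        with pytest.raises(ValidationError):
            similarity_matrix([], db, pathways, "SMC")
        empty_db = Database(compounds=[], contrasts={})
        q = db.contrasts[("R0@1e-06", "SMC")]
        with pytest.raises(ValidationError):
            similarity_matrix([q], empty_db, pathways, "SMC")

    def test_roundtrip_tsv(self, tmp_path):
        records = [
            SimilarityRecord("Q@1", "R0", "PW0", "SMC", 0.5, 7),
            SimilarityRecord("Q@1", "R1", "PW0", "SMC", None, 2),
        ]
        path = tmp_path / "sim.tsv"
        write_similarity(records, path)
        back = read_similarity(path)
        assert back[0].rho == pytest.approx(0.5)
        assert back[1].rho is None and back[1].n_genes == 2

    def test_planted_risk_separation(self, small_cfg, small_db):
        """risk-like query correlates more with risk drugs than non-risk drugs
        on the planted pathways (mean over defined rho values)."""
        from vascrisk.synth import make_query_compound

        database, pathways, truth = small_db
        query = make_query_compound(small_cfg, truth, "risk_like")["SMC"]
        records = similarity_matrix([query], database, pathways, "SMC")
        risk_rho, nonrisk_rho = [], []
        for rec in records:
            if rec.pathway_id in truth.risk_pathway_ids and rec.rho is not None:
                (risk_rho if rec.reference_id in truth.risk_compound_ids else nonrisk_rho).append(rec.rho)
        assert np.mean(risk_rho) > np.mean(nonrisk_rho)
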