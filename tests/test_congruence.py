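"""CADM/Mantel congruence statistics and consensus split pooling."""

import numpy as np
import pytest

from oracles import kendall_w_direct
from phagani.congruence import (
    DistanceMatrixSet, cadm, consensus_splits, gene_distance_set,
    progressive_cadm,
)
from phagani.phylo import Alignment, DistanceMatrix, Split, Tree


def _rand_dm(ids, rng):
    n = len(ids)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(list(ids), m)


IDS = [f"x{i}" for i in range(8)]


class TestCadm:
    def test_identical_matrices_w_one(self):
        rng = np.random.default_rng(0)
        d = _rand_dm(IDS, rng)
        dms = DistanceMatrixSet(IDS, [DistanceMatrix(IDS, d.matrix.copy())
                                      for _ in range(3)], ["a", "b", "c"])
        res = cadm(dms, n_perm=99, seed=1, mantel=False)
        assert res.W == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_reversed_ranks_w_zero(self):
        rng = np.random.default_rng(1)
        m1 = _rand_dm(IDS, rng)
        v = m1.condensed()
        order = np.argsort(v)
        v2 = np.empty_like(v)
        v2[order] = np.sort(v)[::-1]
        iu = np.triu_indices(8, 1)
        m2 = np.zeros((8, 8))
        m2[iu] = v2
        m2 += m2.T
        dms = DistanceMatrixSet(IDS, [m1, DistanceMatrix(IDS, m2)], ["a", "b"])
        res = cadm(dms, n_perm=49, seed=1, mantel=False)
        assert res.W == pytest.approx(0.0, abs=1e-12)

    def test_mean_spearman_identity(self):
        """r_bar == (pW - 1)/(p - 1) to 1e-9 for tie-free matrices."""
        rng = np.random.default_rng(2)
        mats = [_rand_dm(IDS, rng) for _ in range(5)]
        dms = DistanceMatrixSet(IDS, mats, list("abcde"))
        res = cadm(dms, n_perm=0, seed=0, mantel=True, mantel_n_perm=0)
        r_bar = float(res.mantel["r"].mean())
        assert res.mean_spearman == pytest.approx(r_bar, abs=1e-9)

    def test_w_matches_direct_rank_arithmetic(self):
        rng = np.random.default_rng(3)
        mats = [_rand_dm(IDS, rng) for _ in range(4)]
        dms = DistanceMatrixSet(IDS, mats, list("abcd"))
        res = cadm(dms, n_perm=0, seed=0, mantel=False)
        direct = kendall_w_direct([m.condensed() for m in mats])
        assert res.W == pytest.approx(direct, abs=1e-12)

    def test_invariance_under_joint_relabeling(self):
        rng = np.random.default_rng(4)
        mats = [_rand_dm(IDS, rng) for _ in range(3)]
        res1 = cadm(DistanceMatrixSet(IDS, mats, list("abc")), n_perm=0,
                    seed=0, mantel=False)
        perm = np.random.default_rng(9).permutation(8)
        ids2 = [IDS[i] for i in perm]
        mats2 = [DistanceMatrix(ids2, m.matrix[np.ix_(perm, perm)]) for m in mats]
        res2 = cadm(DistanceMatrixSet(ids2, mats2, list("abc")), n_perm=0,
                    seed=0, mantel=False)
        assert res1.W == pytest.approx(res2.W, abs=1e-12)

    def test_clonal_genes_concordant_random_genes_not(self):
        """Genes simulated on one genealogy agree (high W); genes simulated
        on independent genealogies do not (low W)."""
        from phagani.simgenomes import simulate_gene_alignment
        from phagani.phylo import tn93_distance

        ids, mat = simulate_gene_alignment(12, 12_000, 0.05, seed=5)
        same = [tn93_distance(Alignment(ids, mat[:, k * 1200:(k + 1) * 1200]))
                for k in range(10)]
        res_same = cadm(DistanceMatrixSet(ids, same, [f"g{k}" for k in range(10)]),
                        n_perm=99, seed=0, mantel=False)
        indep = []
        for k in range(10):
            ids2, m2 = simulate_gene_alignment(12, 1200, 0.05, seed=600 + k)
            indep.append(tn93_distance(Alignment(ids2, m2)))
        res_ind = cadm(DistanceMatrixSet(ids2, indep, [f"g{k}" for k in range(10)]),
                       n_perm=99, seed=0, mantel=False)
        assert res_same.W > 0.6
        assert res_same.p_value <= 0.01
        assert res_ind.W < 0.2

    def test_requires_enough_taxa_and_matrices(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            cadm(DistanceMatrixSet(IDS[:3], [_rand_dm(IDS[:3], rng)] * 2,
                                   ["a", "b"]))


class TestGeneDistanceSet:
    def test_saturated_gene_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(5)]
        base = rng.integers(0, 4, 400).astype(np.uint8)
        rows = [base.copy() for _ in range(5)]
        for r in rows[1:]:
            sites = rng.choice(400, 15, replace=False)
            r[sites] = (r[sites] + 1) % 4
        good = Alignment(taxa, np.vstack(rows))
        bad = Alignment(taxa, rng.integers(0, 4, (5, 400)).astype(np.uint8))
        import logging

        with caplog.at_level(logging.WARNING, logger="phagani.congruence"):
            dms = gene_distance_set({"good": good, "bad": bad}, taxa)
        assert dms.gene_ids == ["good"]
        assert "bad" in caplog.text

    def test_no_usable_genes_errors(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(4)]
        bad = Alignment(taxa, rng.integers(0, 4, (4, 300)).astype(np.uint8))
        with pytest.raises(ValueError, match="no usable genes"):
            gene_distance_set({"bad": bad}, taxa)


class TestProgressive:
    def test_empty_additions_single_step(self):
        from phagani.simgenomes import simulate_gene_alignment
        ids, mat = simulate_gene_alignment(6, 6000, 0.04, seed=9)

        def alns_for(sample):
            return {f"g{k}": Alignment(ids, mat[:, k * 600:(k + 1) * 600])
                    for k in range(6)}

        res = progressive_cadm(ids, [], alns_for, n_perm=49, seed=0)
        assert len(res.steps) == 1
        assert res.steps[0]["ok"]


class TestConsensusSplits:
    def _trees(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        # one NNI away: swap B and C
        t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        return t1, t2

    def test_identical_trees_weight_one(self):
        t1, _ = self._trees()
        s = consensus_splits([t1, t1.copy()], min_freq=0.0)
        assert all(sp.weight == 1.0 for sp in s.splits)
        assert len(s.splits) == 2

    def test_nni_conflict_half_weights(self):
        t1, t2 = self._trees()
        s = consensus_splits([t1, t2], min_freq=0.0)
        by_side = {sp.side: sp.weight for sp in s.splits}
        assert by_side[frozenset("CD")] == 0.5
        assert by_side[frozenset("BD")] == 0.5

    def test_min_freq_filters(self):
        t1, t2 = self._trees()
        s = consensus_splits([t1, t2], min_freq=0.6)
        assert all(sp.weight >= 0.6 for sp in s.splits)

    def test_taxa_mismatch_errors(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            consensus_splits([t1, t2])

    def test_nexus_export_shape(self):
        t1, t2 = self._trees()
        s = consensus_splits([t1, t2], min_freq=0.0)
        nex = s.to_nexus()
        assert nex.startswith("#NEXUS")
        assert "BEGIN Splits;" in nex
        assert f"nsplits={len(s.splits)}" in nex
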