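"""Fragment ANI: tiling rules, identity recovery, coverage bounds, and the
group/satellite/transfer delineation logic."""

import numpy as np
import pandas as pd
import pytest

from phagani import anib
from phagani.anib import AniMatrix, fragment_genome
from phagani.simgenomes import mutate_fraction


def _mk_matrix(ids, ani_pairs, cov=1.0):
    """Build an AniMatrix from symmetric {frozenset: ani} with flat coverage."""
    ids = list(ids)
    n = len(ids)
    ani = pd.DataFrame(np.full((n, n), 60.0), index=ids, columns=ids)
    covm = pd.DataFrame(np.full((n, n), cov), index=ids, columns=ids)
    for (a, b), v in ani_pairs.items():
        ani.loc[a, b] = ani.loc[b, a] = v
    np.fill_diagonal(ani.values, 100.0)
    np.fill_diagonal(covm.values, 1.0)
    return AniMatrix(ids=list(ids), ani=ani, coverage=covm)


class TestFragmentation:
    def test_exact_multiple(self):
        frags = fragment_genome("A" * 1000, 500)
        assert [(f.start, f.end) for f in frags] == [(0, 500), (500, 1000)]

    def test_trailing_kept_at_half(self):
        frags = fragment_genome("A" * 1250, 500)
        assert [(f.start, f.end) for f in frags] == [(0, 500), (500, 1000),
                                                     (1000, 1250)]

    def test_trailing_discarded_below_half(self):
        frags = fragment_genome("A" * 1100, 500)
        assert len(frags) == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fragment_genome("", 500)

    def test_tiling_is_disjoint_and_ordered(self):
        frags = fragment_genome("ACGT" * 700, 500)
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start
        assert all(f.end - f.start <= 500 for f in frags)


class TestComputeAnib:
    def test_identical_genomes(self):
        rng = np.random.default_rng(0)
        g = "".join(rng.choice(list("ACGT"), 10_000))
        r = anib.compute_anib(g, g)
        assert r.ani == 100.0
        assert r.coverage == 1.0
        assert r.n_qualifying == r.n_fragments

    @pytest.mark.parametrize("d", [0.02, 0.05])
    def test_identity_recovery(self, d):
        """ANI of a pair at exact substitution fraction d is 100(1-d) +- 0.3."""
        rng = np.random.default_rng(1)
        g = "".join(rng.choice(list("ACGT"), 50_000))
        r = anib.compute_anib(g, mutate_fraction(g, d, seed=2))
        assert r.coverage >= 0.99
        assert abs(r.ani - 100 * (1 - d)) <= 0.3

    def test_unrelated_genomes_low_coverage(self):
        g1 = "".join(np.random.default_rng(1).choice(list("ACGT"), 50_000))
        g2 = "".join(np.random.default_rng(2).choice(list("ACGT"), 50_000))
        r = anib.compute_anib(g1, g2)
        assert r.coverage < 0.02

    def test_no_qualifying_is_none_not_zero(self):
        r = anib.compute_anib("ACGT" * 250, "TTTT" * 250)
        assert r.ani is None
        assert r.coverage == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            anib.compute_anib("", "ACGT")


class TestComputeAll:
    def test_counts_and_symmetrization(self):
        rng = np.random.default_rng(3)
        g = "".join(rng.choice(list("ACGT"), 6000))
        genomes = {"a": g, "b": mutate_fraction(g, 0.03, 1), "c": g}
        m = anib.compute_all(genomes)
        off = [(q, t) for q in m.ids for t in m.ids if q != t]
        assert len(off) == 6
        assert m.sym_ani.loc["a", "b"] == pytest.approx(
            (m.ani.loc["a", "b"] + m.ani.loc["b", "a"]) / 2)
        assert m.sym_ani.loc["a", "c"] == 100.0
        pd.testing.assert_frame_equal(m.sym_ani, m.sym_ani.T)

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError):
            anib.compute_all({"a": "ACGT" * 200})


class TestDelineation:
    def test_two_pairs(self):
        m = _mk_matrix("ABCD", {("A", "B"): 95, ("C", "D"): 96, ("A", "C"): 75})
        p = anib.delineate_groups(m)
        assert p.groups == [["A", "B"], ["C", "D"]]
        assert p.singletons == []

    def test_chain_is_one_group(self):
        m = _mk_matrix("ABC", {("A", "B"): 93, ("B", "C"): 93, ("A", "C"): 90})
        p = anib.delineate_groups(m)
        assert p.groups == [["A", "B", "C"]]

    def test_all_below_cutoff_all_singletons(self):
        m = _mk_matrix("ABC", {("A", "B"): 80})
        p = anib.delineate_groups(m)
        assert p.groups == []
        assert p.singletons == ["A", "B", "C"]

    def test_low_coverage_edge_excluded(self):
        """A 95 % ANI pair sharing only 10 % of the genome must not group."""
        m = _mk_matrix("AB", {("A", "B"): 95}, cov=0.1)
        p = anib.delineate_groups(m)
        assert p.groups == []

    def test_satellite_of_one_group(self):
        m = _mk_matrix("ABE", {("A", "B"): 95, ("A", "E"): 88, ("B", "E"): 84})
        p = anib.delineate_groups(m)
        sats = anib.find_satellites(m, p)
        assert sats == [{"genome": "E", "group_index": 0, "max_ani": 88.0}]

    def test_satellite_of_two_groups(self):
        m = _mk_matrix("ABCDE", {("A", "B"): 95, ("C", "D"): 95,
                                 ("E", "A"): 88, ("E", "C"): 87})
        p = anib.delineate_groups(m)
        sats = anib.find_satellites(m, p)
        assert {(s["genome"], s["group_index"]) for s in sats} == {("E", 0), ("E", 1)}

    def test_transfer_candidates(self):
        ids = ["A", "B"]
        ani = pd.DataFrame([[100.0, 96.0], [95.0, 100.0]], index=ids, columns=ids)
        cov = pd.DataFrame([[1.0, 0.15], [0.18, 1.0]], index=ids, columns=ids)
        m = AniMatrix(ids=ids, ani=ani, coverage=cov)
        flags = anib.flag_transfer_candidates(m)
        assert {(f["query"], f["target"]) for f in flags} == {("A", "B"), ("B", "A")}

    def test_full_coverage_pair_not_flagged(self):
        m = _mk_matrix("AB", {("A", "B"): 95}, cov=1.0)
        assert anib.flag_transfer_candidates(m) == []


class TestReport:
    def test_histogram_rows_and_range(self):
        m = _mk_matrix("ABC", {("A", "B"): 95})
        hist, pairs = anib.ani_report(m)
        assert hist.bin_lo.iloc[0] == 60.0
        assert hist.bin_hi.iloc[-1] == 100.0
        assert len(pairs) == 6
        assert hist["count"].sum() == 6


class TestSimulatedRecovery:
    def test_group_recovery_and_satellites(self, three_group_sample,
                                           three_group_matrix):
        """On the designed three-group sample the 92 % partition matches the
        truth exactly and satellites land in the intermediate ANI band."""
        _, _, truth = three_group_sample
        m = three_group_matrix
        p = anib.delineate_groups(m)
        inferred = {frozenset(g) for g in p.groups}
        expected = {frozenset(g for g, lab in truth.labels.items() if lab == name)
                    for name in "ABC"}
        assert inferred == expected
        sats = anib.find_satellites(m, p)
        assert {s["genome"] for s in sats} == {"A_sat0", "B_sat0"}
        for s in sats:
            assert 85.0 <= s["max_ani"] < 92.0

    def test_ani_tracks_divergence(self, three_group_sample, three_group_matrix):
        """Within-group symmetrized ANI ~ 100(1-d) for realized divergence d."""
        _, _, truth = three_group_sample
        m = three_group_matrix
        members = [g for g, lab in truth.labels.items() if lab in ("A", "B", "C")]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if truth.labels[a] != truth.labels[b]:
                    continue
                d = truth.divergence.loc[a, b]
                assert abs(m.sym_ani.loc[a, b] - 100 * (1 - d)) <= 0.6
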