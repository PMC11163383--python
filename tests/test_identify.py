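from itertools import combinations

import numpy as np
import pytest

from stcomplex.identify import (
    ReweightedPIN,
    adhesion_score,
    attach_proteins,
    density_score,
    identify_complexes,
    mine_cores,
    reweight,
)
from stcomplex.io import LocalizationTable
from stcomplex.mhpin import ActivityProfile


def _pin(weighted_edges):
    weights, adjacency = {}, {}
    for a, b, w in weighted_edges:
        key = (a, b) if a < b else (b, a)
        weights[key] = w
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    return ReweightedPIN(weights, adjacency)


def _activity(times_by_protein):
    return {
        p: ActivityProfile(p, 0.0, 0.0, 0.0, frozenset(ts))
        for p, ts in times_by_protein.items()
    }


class TestReweight:
    def test_cosine_on_edges_zero_elsewhere(self):
        emb = {
            "A": np.array([1.0, 0.0]),
            "B": np.array([2.0, 0.0]),  # parallel to A -> cosine 1
            "C": np.array([0.0, 3.0]),  # orthogonal to A -> cosine 0
            "D": np.array([1.0, 0.0]),
        }
        w = reweight(emb, [("A", "B"), ("A", "C")])
        assert w.weight("A", "B") == pytest.approx(1.0)
        assert w.weight("A", "C") == pytest.approx(0.0)
        # D is embedded identically to A but shares no edge
        assert w.weight("A", "D") == 0.0

    def test_missing_embedding_lists_proteins(self):
        with pytest.raises(ValueError, match="B"):
            reweight({"A": np.ones(2)}, [("A", "B")])


class TestDensityScore:
    def test_triangle_with_uniform_weights(self):
        w = _pin([("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.5)])
        assert density_score({"A", "B", "C"}, w) == pytest.approx(1.5)

    def test_zero_weights_give_zero(self):
        w = _pin([("A", "B", 0.0)])
        assert density_score({"A", "B"}, w) == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        names = list("ABCDEF")
        edges = [
            (a, b, float(rng.uniform(-1, 1)))
            for a, b in combinations(names, 2)
            if rng.random() < 0.7
        ]
        w = _pin(edges)
        for size in (2, 4, 6):
            core = set(rng.choice(names, size=size, replace=False))
            expected = sum(
                w.weight(a, b) for a, b in combinations(sorted(core), 2)
            )
            assert density_score(core, w) == pytest.approx(expected)


class TestAdhesionScore:
    def test_mean_weight_into_core(self):
        w = _pin([("p", "A", 0.6), ("p", "B", 0.6)])
        assert adhesion_score("p", {"A", "B", "C"}, w) == pytest.approx(0.4)

    def test_no_edges_gives_zero(self):
        w = _pin([("A", "B", 0.9)])
        assert adhesion_score("p", {"A", "B"}, w) == 0.0

    def test_full_weights_give_one(self):
        w = _pin([("p", "A", 1.0), ("p", "B", 1.0)])
        assert adhesion_score("p", {"A", "B"}, w) == pytest.approx(1.0)

    def test_core_member_rejected(self):
        w = _pin([("A", "B", 1.0)])
        with pytest.raises(ValueError):
            adhesion_score("A", {"A", "B"}, w)


class TestMineCores:
    def test_two_disjoint_triangles(self):
        w = _pin(
            [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9),
             ("X", "Y", 0.5), ("Y", "Z", 0.5), ("X", "Z", 0.5)]
        )
        cores = mine_cores(w)
        assert [c for c, _ in cores] == [
            frozenset({"A", "B", "C"}),
            frozenset({"X", "Y", "Z"}),
        ]

    def test_overlapping_weaker_clique_deleted(self):
        # strong 4-clique ABCD; weaker clique BCDE overlaps it and keeps
        # only one non-overlapping node (E) -> deleted at the pruning step
        strong = [("A", "B", 0.9), ("A", "C", 0.9), ("A", "D", 0.9),
                  ("B", "C", 0.9), ("B", "D", 0.9), ("C", "D", 0.9)]
        weak = [("B", "E", 0.1), ("C", "E", 0.1), ("D", "E", 0.1)]
        w = _pin(strong + weak)
        cores = mine_cores(w)
        assert [c for c, _ in cores] == [frozenset({"A", "B", "C", "D"})]

    def test_overlapping_clique_remainder_kept(self):
        # two 4-cliques sharing one node: the weaker one keeps a 3-node
        # remainder, which re-enters the candidate pool
        c1 = [("A", "B", 0.9), ("A", "C", 0.9), ("A", "D", 0.9),
              ("B", "C", 0.9), ("B", "D", 0.9), ("C", "D", 0.9)]
        c2 = [("D", "X", 0.4), ("D", "Y", 0.4), ("D", "Z", 0.4),
              ("X", "Y", 0.4), ("X", "Z", 0.4), ("Y", "Z", 0.4)]
        w = _pin(c1 + c2)
        cores = mine_cores(w)
        assert [c for c, _ in cores] == [
            frozenset({"A", "B", "C", "D"}),
            frozenset({"X", "Y", "Z"}),
        ]

    def test_coactivity_excludes_incoherent_clique(self):
        w = _pin([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)])
        activity = _activity({"A": {1}, "B": {2}, "C": {3}})
        loc = LocalizationTable({})
        assert len(mine_cores(w, activity, loc)) == 0
        # a shared compartment rescues the same clique (OR semantics)
        loc2 = LocalizationTable({p: frozenset({"nucleus"}) for p in "ABC"})
        assert len(mine_cores(w, activity, loc2)) == 1

    def test_negative_weight_edges_not_in_mining_graph(self):
        w = _pin([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", -0.1)])
        assert len(mine_cores(w)) == 0

    def test_invariant_to_edge_ordering(self):
        rng = np.random.default_rng(1)
        names = [f"n{i}" for i in range(12)]
        edges = [
            (a, b, float(rng.uniform(0.1, 1.0)))
            for a, b in combinations(names, 2)
            if rng.random() < 0.45
        ]
        baseline = [c for c, _ in mine_cores(_pin(edges))]
        for _ in range(3):
            rng.shuffle(edges)
            assert [c for c, _ in mine_cores(_pin(edges))] == baseline


class TestAttachment:
    def _core_setup(self, sat_weight):
        core_edges = [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)]
        sat = [("A", "s", sat_weight), ("B", "s", sat_weight)]
        return _pin(core_edges + sat)

    def test_lambda_one_blocks_attachment(self):
        w = self._core_setup(1.0)
        out = identify_complexes(
            {p: np.ones(2) for p in "ABCs"},
            [("A", "B"), ("B", "C"), ("A", "C"), ("A", "s"), ("B", "s")],
            lam=1.0,
        )
        # cosine weights are 1 but the mean into the 3-core is 2/3 < 1
        assert out[0].members == frozenset({"A", "B", "C"})

    def test_lambda_zero_attaches_any_positive_neighbor(self):
        w = self._core_setup(0.1)
        cores = mine_cores(w)
        out = attach_proteins(cores, w, lam=0.0)
        assert out[0].members == frozenset({"A", "B", "C", "s"})
        assert out[0].core == frozenset({"A", "B", "C"})

    def test_high_affinity_satellite_at_default_lambda(self):
        # s attaches with mean weight (0.9+0.9+0)/3 = 0.6 > 0.4
        w = self._core_setup(0.9)
        out = attach_proteins(mine_cores(w), w, lam=0.4)
        assert out[0].members == frozenset({"A", "B", "C", "s"})
        # a colder satellite (mean 0.2) stays out
        w2 = self._core_setup(0.3)
        out2 = attach_proteins(mine_cores(w2), w2, lam=0.4)
        assert out2[0].members == frozenset({"A", "B", "C"})

    def test_attachments_recheckable_post_hoc(self):
        rng = np.random.default_rng(2)
        names = [f"n{i}" for i in range(14)]
        edges = [
            (a, b, float(rng.uniform(-0.2, 1.0)))
            for a, b in combinations(names, 2)
            if rng.random() < 0.4
        ]
        w = _pin(edges)
        lam = 0.4
        out = attach_proteins(mine_cores(w), w, lam)
        for c in out:
            assert len(c.core) >= 3
            for p in c.members - c.core:
                assert adhesion_score(p, c.core, w) > lam

    def test_duplicate_complexes_removed(self):
        # two identical triangles in the candidate pool collapse to one
        w = _pin([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)])
        cores = mine_cores(w)
        cores.cores.append((frozenset({"A", "B", "C"}), 2.7))
        out = attach_proteins(cores, w, lam=0.4)
        assert len(out) == 1
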