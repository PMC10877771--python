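"""Clone maps: CCF projection, spread direction, polyclonality, seeding."""

import numpy as np
import pytest

import clonetracer as ct
from clonetracer.clonemap import (build_clone_map, classify_polyclonal,
                                  correct_ccfs, infer_seeding,
                                  infer_transition)
from conftest import make_clusters


def _tree(spec, parent, samples=("S1", "S2")):
    clusters = make_clusters(spec, samples=samples)
    return clusters, ct.CloneTree(clusters, parent,
                                  ct.score_tree(parent, clusters))


class TestCorrectCcfs:
    def test_consistent_vector_unchanged(self):
        clusters, tree = _tree(
            [("A", 30, 1.0, 1.0), ("B", 20, 0.6, 0.2), ("C", 10, 0.3, 0.1)],
            {"A": None, "B": "A", "C": "B"})
        out = correct_ccfs(clusters, tree)
        assert out["S1"] == {"A": 1.0, "B": 0.6, "C": 0.3}
        assert out["S2"] == {"A": 1.0, "B": 0.2, "C": 0.1}

    def test_offending_siblings_scaled_proportionally(self):
        clusters, tree = _tree(
            [("A", 30, 0.6), ("B", 20, 0.4), ("C", 10, 0.3)],
            {"A": None, "B": "A", "C": "A"}, samples=("S1",))
        out = correct_ccfs(clusters, tree)
        assert out["S1"]["B"] == pytest.approx(0.4 * 6 / 7)
        assert out["S1"]["C"] == pytest.approx(0.3 * 6 / 7)

    def test_flagged_clonal_clipped_to_one(self):
        clusters, tree = _tree(
            [("A", 30, 1.05, 1.0), ("B", 20, 0.5, 0.5)],
            {"A": None, "B": "A"})
        out = correct_ccfs(clusters, tree)
        assert out["S1"]["A"] == 1.0

    def test_cascades_down_the_tree(self):
        # scaling B's children must respect B's own scaled value
        clusters, tree = _tree(
            [("A", 40, 1.0), ("B", 30, 1.2), ("C", 20, 0.9), ("D", 10, 0.6)],
            {"A": None, "B": "A", "C": "B", "D": "B"}, samples=("S1",))
        out = correct_ccfs(clusters, tree)["S1"]
        assert out["B"] == 1.0  # clipped
        assert out["C"] + out["D"] <= out["B"] + 1e-9
        assert out["C"] / out["D"] == pytest.approx(0.9 / 0.6)

    def test_nesting_invariant_on_simulated_cohorts(self):
        """Post-correction, children never outsum parents; all in [0,1]."""
        for seed in range(20):
            K = 4 + seed % 3
            parent_idx = ct.simulate_tree(K, seed=seed)
            rng = np.random.default_rng(seed)
            _, ccf = ct.simulate_ccfs(parent_idx, S=2, seed=seed)
            noisy = np.clip(ccf + rng.normal(0, 0.05, ccf.shape), 0, None)
            labels = [chr(ord("A") + i) for i in range(K)]
            clusters = make_clusters(
                [(labels[i], 20, *noisy[:, i]) for i in range(K)])
            pmap = {labels[i]: (labels[p] if p >= 0 else None)
                    for i, p in enumerate(parent_idx)}
            tree = ct.CloneTree(clusters, pmap,
                                ct.score_tree(pmap, clusters))
            out = correct_ccfs(clusters, tree)
            for s, vals in out.items():
                assert all(0 <= v <= 1 for v in vals.values())
                for lab in labels:
                    kids = tree.children(lab)
                    if kids:
                        assert sum(vals[k] for k in kids) \
                            <= vals[lab] + 1e-9


def _fig_style_map(j_ccf=(0.26, 1.0)):
    """Two samples; clone J subclonal in S1, clonal in S2, nested under A."""
    clusters, tree = _tree(
        [("A", 50, 1.0, 1.0), ("J", 30, j_ccf[0], j_ccf[1]),
         ("E", 10, 0.1, 0.4)],
        {"A": None, "J": "A", "E": "J"})
    return build_clone_map(clusters, tree)


class TestInferTransition:
    def test_subclonal_to_clonal_rise_gives_direction(self):
        """A clone at CCF 0.26 in one sample and 1.00 in another orients
        the spread from the first sample to the second."""
        cmap = _fig_style_map()
        t = infer_transition("S1", "S2", cmap)
        assert t is not None
        assert (t.source, t.target) == ("S1", "S2")
        assert "J" in t.supporting_clones

    def test_identical_compositions_give_none(self):
        clusters, tree = _tree(
            [("A", 50, 1.0, 1.0), ("B", 30, 0.5, 0.5)],
            {"A": None, "B": "A"})
        cmap = build_clone_map(clusters, tree)
        assert infer_transition("S1", "S2", cmap) is None

    def test_unknown_sample_rejected(self):
        cmap = _fig_style_map()
        with pytest.raises(KeyError):
            infer_transition("S1", "SX", cmap)

    def test_nesting_guard_blocks_clonal_clone_loss(self):
        # B rises to fixation in S2 but C, clonal in S1, vanishes: the
        # clone-set nesting guard refuses to order the pair. Such a
        # composition cannot arise from the tree-consistent projection
        # (a clonal competitor caps any rising clone below delta), so the
        # guard is exercised on a hand-built map.
        clusters, tree = _tree(
            [("A", 50, 1.0, 1.0), ("B", 30, 0.3, 1.0), ("C", 20, 0.95, 0.0)],
            {"A": None, "B": "A", "C": "A"})
        cmap = ct.CloneMap(
            ["S1", "S2"], tree,
            corrected={"S1": {"A": 1.0, "B": 0.3, "C": 0.95},
                       "S2": {"A": 1.0, "B": 1.0, "C": 0.0}},
            raw={})
        assert infer_transition("S1", "S2", cmap) is None

    def test_antisymmetric_on_simulated_pairs(self):
        """Planted parent/daughter sample pairs: direction matches truth."""
        good = attempts = 0
        for seed in range(100):
            K = 5
            parent_idx = ct.simulate_tree(K, seed=seed)
            try:
                _, ccf = ct.simulate_ccfs(parent_idx, S=1, seed=seed,
                                          sparsity=0.0, min_separation=0.1)
            except RuntimeError:
                continue
            # daughter sample: pick a clone subclonal in the parent sample
            # and fix its whole lineage (CCF 1), zeroing other branches
            labels = [chr(ord("A") + i) for i in range(K)]
            cands = [i for i in range(1, K)
                     if 0.15 < ccf[0, i] < 0.85]
            if not cands:
                continue
            chosen = cands[0]
            lineage = {chosen}
            p = parent_idx[chosen]
            while p >= 0:
                lineage.add(p)
                p = parent_idx[p]
            daughter = np.array([1.0 if i in lineage else 0.0
                                 for i in range(K)])
            med = np.column_stack([ccf[0], daughter])
            clusters = make_clusters(
                [(labels[i], 20, *med[i]) for i in range(K)])
            pmap = {labels[i]: (labels[p] if p >= 0 else None)
                    for i, p in enumerate(parent_idx)}
            tree = ct.CloneTree(clusters, pmap,
                                ct.score_tree(pmap, clusters))
            cmap = build_clone_map(clusters, tree)
            attempts += 1
            t = infer_transition("S1", "S2", cmap)
            if t is not None:
                assert (t.source, t.target) == ("S1", "S2")
                good += 1
        # most planted pairs are unambiguous; none points backwards
        assert attempts >= 30 and good >= attempts * 0.5


class TestClassifyPolyclonal:
    def test_two_present_siblings(self):
        clusters, tree = _tree(
            [("A", 50, 1.0), ("B", 30, 0.4), ("C", 20, 0.3)],
            {"A": None, "B": "A", "C": "A"}, samples=("S1",))
        cmap = build_clone_map(clusters, tree)
        assert classify_polyclonal("S1", cmap) is True

    def test_pure_chain_is_monoclonal(self):
        clusters, tree = _tree(
            [("A", 50, 1.0), ("B", 30, 0.6), ("C", 20, 0.3)],
            {"A": None, "B": "A", "C": "B"}, samples=("S1",))
        cmap = build_clone_map(clusters, tree)
        assert classify_polyclonal("S1", cmap) is False

    def test_sibling_below_delta_does_not_count(self):
        clusters, tree = _tree(
            [("A", 50, 1.0), ("B", 30, 0.4), ("C", 20, 0.05)],
            {"A": None, "B": "A", "C": "A"}, samples=("S1",))
        cmap = build_clone_map(clusters, tree)
        assert classify_polyclonal("S1", cmap, delta=0.10) is False


class TestInferSeeding:
    def _map(self, med, parent, sizes=None, samples=("P1", "MET")):
        K = len(med)
        labels = [chr(ord("A") + i) for i in range(K)]
        sizes = sizes or [50 - i for i in range(K)]
        clusters = make_clusters(
            [(labels[i], sizes[i], *med[i]) for i in range(K)],
            samples=samples)
        pmap = {labels[i]: (labels[p] if p >= 0 else None)
                for i, p in enumerate(parent)}
        tree = ct.CloneTree(clusters, pmap, ct.score_tree(pmap, clusters))
        return build_clone_map(clusters, tree)

    def test_single_leaf_lineage(self):
        # met = lineage of leaf C fixed
        cmap = self._map([(1.0, 1.0), (0.5, 1.0), (0.2, 1.0)],
                         [-1, 0, 1])
        call = infer_seeding("MET", cmap, primary_samples=["P1"])
        assert call.clones == ["C"]
        assert not call.multiple
        assert call.candidate_sources["C"] == ["P1"]

    def test_two_disjoint_branches_multiple_seeding(self):
        # clones B and C on different branches both present in the met
        cmap = self._map([(1.0, 1.0), (0.5, 0.6), (0.3, 0.4)],
                         [-1, 0, 0])
        call = infer_seeding("MET", cmap, primary_samples=["P1"])
        assert call.clones == ["B", "C"]
        assert call.multiple

    def test_truncal_only_met(self):
        # met contains only the ancestral clone (cf. a trunk-seeded node)
        cmap = self._map([(1.0, 1.0), (0.5, 0.0), (0.3, 0.0)],
                         [-1, 0, 0])
        call = infer_seeding("MET", cmap, primary_samples=["P1"])
        assert call.clones == ["A"]
        assert not call.multiple

    def test_planted_seeding_recovered_over_cohorts(self):
        """Planted single/double seeding recovered whenever CCF > delta."""
        for seed in range(100):
            K = 6
            parent_idx = ct.simulate_tree(K, seed=seed)
            # choose one or two pairwise incomparable non-root clones
            rng = np.random.default_rng(seed)
            n_events = 1 + seed % 2
            anc = []
            for i in range(K):
                a, p = set(), parent_idx[i]
                while p >= 0:
                    a.add(p)
                    p = parent_idx[p]
                anc.append(a)
            cands = list(range(1, K))
            rng.shuffle(cands)
            planted = []
            for c in cands:
                if all(c not in anc[o] and o not in anc[c]
                       for o in planted):
                    planted.append(c)
                if len(planted) == n_events:
                    break
            share = 1.0 / len(planted)
            met = np.zeros(K)
            for c in planted:
                met[c] += share
                for a in anc[c]:
                    met[a] += share
            primary = np.linspace(1.0, 0.3, K)  # clone i present in P1
            labels = [chr(ord("A") + i) for i in range(K)]
            clusters = make_clusters(
                [(labels[i], 30, primary[i], met[i]) for i in range(K)],
                samples=("P1", "MET"))
            pmap = {labels[i]: (labels[p] if p >= 0 else None)
                    for i, p in enumerate(parent_idx)}
            tree = ct.CloneTree(clusters, pmap,
                                ct.score_tree(pmap, clusters))
            cmap = build_clone_map(clusters, tree)
            call = infer_seeding("MET", cmap, primary_samples=["P1"])
            want = sorted(labels[c] for c in planted if met[c] > 0.10)
            assert call.clones == want
            assert call.multiple == (len(want) > 1)


def test_build_clone_map_assembles_all_inferences():
    clusters, tree = _tree(
        [("A", 50, 1.0, 1.0), ("B", 30, 0.4, 1.0), ("C", 20, 0.3, 0.0)],
        {"A": None, "B": "A", "C": "A"})
    cmap = build_clone_map(clusters, tree,
                           sites={"S1": "prostate", "S2": "lymph_node"})
    assert cmap.polyclonal["S1"] is True
    assert len(cmap.seeding) == 1
    assert cmap.seeding[0].met_sample == "S2"
    assert cmap.seeding[0].clones == ["B"]
    # composition respects ancestry: every present clone's parent present
    comp = cmap.composition("S1")
    for label in comp:
        p = tree.parent[label]
        assert p is None or p in comp
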