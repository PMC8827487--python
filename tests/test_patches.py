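"""Descriptor computation and seed/extend/outer patch growth."""

import numpy as np
import pytest

from ccd2pi.docking import ConformationStore, DockingConformation, RigidTransform
from ccd2pi.fixtures import designed_descriptors, make_toy_surface
from ccd2pi.interfaces import Interface
from ccd2pi.patches import (STRATEGIES, DescriptorTable, circular_variance,
                            conservation_entropy_fallback, consensus_patches,
                            grow_patch, nip_from_docking, pc_from_resnames,
                            select_reference_interface)


class TestCircularVariance:
    def test_colinear_neighbours_give_zero(self):
        ca = np.array([[0.0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0]])
        assert circular_variance(ca, 0) == pytest.approx(0.0)

    def test_isotropic_neighbours_give_one(self):
        ca = np.array([[0.0, 0, 0], [5, 0, 0], [-5, 0, 0], [0, 5, 0],
                       [0, -5, 0], [0, 0, 5], [0, 0, -5]])
        assert circular_variance(ca, 0) == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_cloud(self, rng):
        ca = rng.normal(0, 6, (25, 3))
        for res in (0, 7, 19):
            got = circular_variance(ca, res, radius=12.0)
            vecs = []
            for j in range(25):
                if j == res:
                    continue
                d = ca[j] - ca[res]
                n = np.linalg.norm(d)
                if 0 < n <= 12.0:
                    vecs.append(d / n)
            expected = (1 - np.linalg.norm(np.sum(vecs, axis=0)) / len(vecs)
                        if vecs else 0.0)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_isolated_residue_warns(self):
        ca = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        with pytest.warns(UserWarning):
            assert circular_variance(ca, 0) == 0.0


class TestDescriptors:
    def test_range_validation_on_surface(self):
        n = 5
        with pytest.raises(ValueError, match="tjet"):
            DescriptorTable(tjet=np.full(n, 1.5), pc=np.zeros(n), cv=np.zeros(n),
                            nip=np.zeros(n), surface=np.ones(n, bool))
        # out-of-range off surface is tolerated
        t = np.array([0.5, 0.5, 9.0])
        DescriptorTable(tjet=t, pc=np.zeros(3), cv=np.zeros(3), nip=np.zeros(3),
                        surface=np.array([True, True, False]))

    def test_stage_score_product_with_inverted_cv(self):
        d = DescriptorTable(tjet=np.array([0.5]), pc=np.array([0.4]),
                            cv=np.array([0.25]), nip=np.array([0.8]),
                            surface=np.ones(1, bool))
        assert d.stage_score(("tjet", "cv", "nip")) == pytest.approx(
            0.5 * 0.75 * 0.8)

    def test_pc_table_covers_standard_residues(self):
        vals = pc_from_resnames(["TRP", "LYS", "GLY"])
        assert np.all((vals >= 0) & (vals <= 1))
        assert vals[0] > vals[1]     # aromatics favoured over lysine

    def test_entropy_fallback_extremes(self):
        cons = conservation_entropy_fallback(["AAA", "AAC", "AAG"])
        assert cons[0] == pytest.approx(1.0)
        assert cons[2] < 1.0


def _store_with_planted_interfaces(counts, n_res=6):
    """Pair p/qK stores where residue r of p appears in `counts[r]` top poses."""
    from ccd2pi.fixtures import _dummy_protein

    store = ConformationStore(proteins={"p": _dummy_protein("p", n_res, 0.0)})
    pose = 0
    pair_confs = []
    for r, c in enumerate(counts):
        for _ in range(c):
            pair_confs.append(DockingConformation(
                "p", "q", pose, RigidTransform.identity(), -1.0,
                docked_interface=({r}, {0})))
            pose += 1
    store.proteins["q"] = store.proteins["p"]
    store.pairs[("p", "q")] = pair_confs
    return store


class TestNip:
    def test_counts_normalized_by_maximum(self):
        counts = [4, 2, 0, 1, 0, 0]
        store = _store_with_planted_interfaces(counts)
        nip = nip_from_docking(store, "p", top_k=len(store.pairs[("p", "q")]))
        assert nip == pytest.approx(np.array(counts) / 4)

    def test_everywhere_and_nowhere(self):
        store = _store_with_planted_interfaces([3, 0, 0])
        nip = nip_from_docking(store, "p", top_k=3)
        assert nip[0] == 1.0 and nip[1] == 0.0

    def test_missing_protein_errors(self):
        store = _store_with_planted_interfaces([1])
        with pytest.raises(KeyError):
            nip_from_docking(store, "absent")


class TestGrowPatch:
    @pytest.fixture()
    def separable(self, toy_surface):
        graph, itf = toy_surface
        n = len(graph.ca_coords)
        cluster = itf.residues            # compact designed cap
        base = np.zeros(n)
        base[list(cluster)] = 1.0
        d = DescriptorTable(tjet=base.copy(), pc=base.copy(), cv=1 - base,
                            nip=base.copy(), surface=np.ones(n, bool))
        return graph, d, cluster

    @pytest.mark.parametrize("strategy", list(STRATEGIES))
    def test_separable_signal_recovered_by_every_scheme(self, separable, strategy):
        graph, d, cluster = separable
        for scheme in STRATEGIES[strategy].schemes:
            patch = grow_patch(graph, d, scheme, seed=0)
            assert patch == cluster

    def test_dockseed_without_nip_gives_empty_patch(self, separable):
        graph, d, _ = separable
        d.nip = np.zeros_like(d.nip)
        scheme = STRATEGIES["SC-dockSeed-mix"].schemes[0]
        with pytest.warns(UserWarning, match="no seed"):
            assert grow_patch(graph, d, scheme, seed=0) == frozenset()

    def test_seed_stage_matches_independent_rule(self, toy_surface, rng):
        """Seed = connected top-percentile cluster holding the best residue."""
        graph, _ = toy_surface
        n = len(graph.ca_coords)
        score = rng.uniform(0.01, 1.0, n)       # gradient field, all positive
        # pc = 0 silences the extension/outer stages (their products vanish)
        d = DescriptorTable(tjet=score, pc=np.zeros(n), cv=np.zeros(n),
                            nip=np.zeros(n), surface=np.ones(n, bool))
        scheme = STRATEGIES["SC-juxt"].schemes[0]       # seed on tjet only
        patch = grow_patch(graph, d, scheme, seed=0)
        thr = np.percentile(score, 85.0)
        admitted = {r for r in range(n) if score[r] >= thr}
        # independent connected-component search from the argmax
        best = int(np.argmax(score))
        comp, frontier = {best}, [best]
        while frontier:
            r = frontier.pop()
            for nb in graph.neighbors(r):
                if nb in admitted and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        assert patch == frozenset(comp)


class TestConsensus:
    def test_deterministic_field_consensus_equals_single_run(self, toy_surface):
        graph, itf = toy_surface
        n = len(graph.ca_coords)
        d = designed_descriptors(n, np.ones(n, bool), itf.residues)
        pred = consensus_patches(graph, d, "SC-dockSeed-mix", seed=4)
        single = grow_patch(graph, d, STRATEGIES["SC-dockSeed-mix"].schemes[0], 0)
        union = frozenset().union(*pred.patches)
        assert union == single == itf.residues

    def test_vote_threshold_at_least_two(self, toy_surface):
        graph, itf = toy_surface
        n = len(graph.ca_coords)
        d = designed_descriptors(n, np.ones(n, bool), itf.residues, noise=0.35,
                                 seed=9)
        pred = consensus_patches(graph, d, "SC-mix", seed=9)
        assert all(v >= 2 for v in
                   (pred.votes[r] for p in pred.patches for r in p))

    def test_same_seed_identical_prediction(self, toy_surface):
        graph, itf = toy_surface
        n = len(graph.ca_coords)
        d = designed_descriptors(n, np.ones(n, bool), itf.residues, noise=0.3,
                                 seed=2)
        p1 = consensus_patches(graph, d, "SC-mix", seed=7)
        p2 = consensus_patches(graph, d, "SC-mix", seed=7)
        assert p1.patches == p2.patches and p1.votes == p2.votes

    def test_raising_vote_threshold_never_enlarges(self, toy_surface):
        from dataclasses import replace

        graph, itf = toy_surface
        n = len(graph.ca_coords)
        d = designed_descriptors(n, np.ones(n, bool), itf.residues, noise=0.4,
                                 seed=3)
        sets = []
        for cmin in (2, 4, 6):
            strat = replace(STRATEGIES["SC-mix"], consensus_min=cmin)
            pred = consensus_patches(graph, d, strat, seed=5)
            sets.append(frozenset().union(*pred.patches) if pred.patches
                        else frozenset())
        assert sets[0] >= sets[1] >= sets[2]


class TestSelectReferenceInterface:
    def _prediction(self, patches):
        from ccd2pi.patches import PatchPrediction

        return PatchPrediction("p", [frozenset(p) for p in patches])

    def test_single_patch_equal_to_known(self):
        known = Interface("p", frozenset({1, 2, 3}))
        pred = self._prediction([{1, 2, 3}])
        ri = select_reference_interface(pred, "oracle", known)
        assert ri.residues == known.residues

    def test_union_beats_single_patches(self):
        known = Interface("p", frozenset(range(10)))
        pred = self._prediction([{0, 1, 2, 3, 11}, {4, 5, 6}])
        ri = select_reference_interface(pred, "oracle", known)
        assert ri.residues == frozenset({0, 1, 2, 3, 11, 4, 5, 6})
        # oracle F1 >= F1 of any single patch, by exhaustive enumeration
        from ccd2pi.interfaces import interface_agreement

        best_single = max(interface_agreement(Interface("p", p, "predicted"),
                                              known)[0] for p in pred.patches)
        oracle_f1 = interface_agreement(ri, known)[0]
        assert oracle_f1 >= best_single

    def test_blind_mode_returns_union(self):
        pred = self._prediction([{1, 2}, {7, 8}])
        ri = select_reference_interface(pred, "blind")
        assert ri.residues == frozenset({1, 2, 7, 8})
        assert ri.provenance == "predicted"

    def test_oracle_requires_known(self):
        with pytest.raises(ValueError):
            select_reference_interface(self._prediction([{1}]), "oracle")

    def test_no_patches_warns_empty(self):
        with pytest.warns(UserWarning):
            ri = select_reference_interface(self._prediction([]), "blind")
        assert len(ri.residues) == 0
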