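"""Fitch scoring, exhaustive fossil placement and the character bootstrap."""

import numpy as np
import pytest

import fossilplace as fp
from fossilplace.matrices import CharacterMatrix
from fossilplace.parsimony import bootstrap_replicate_indices
from fossilplace.splits import tree_to_splits
from fossilplace.trees import TaxonSet, canonical_split

from _oracles import brute_fitch, random_matrix, random_tree


def single_char_matrix(assignments, k):
    taxa = TaxonSet(list(assignments))
    rows = {t: (frozenset(s) if isinstance(s, (set, frozenset)) else frozenset([s]),)
            for t, s in assignments.items()}
    return CharacterMatrix(taxa=taxa, rows=rows, state_space=(k,))


class TestFitch:
    def test_constant_character_zero_steps(self):
        t = fp.read_newick("((A,B),(C,(D,E)));")
        m = single_char_matrix({l: 0 for l in "ABCDE"}, 2)
        assert fp.fitch_steps(t, m) == 0

    def test_quartet_single_change(self):
        t = fp.read_newick("((A,B),(C,D));")
        m = single_char_matrix({"A": 0, "B": 0, "C": 1, "D": 1}, 2)
        assert fp.fitch_steps(t, m) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_labeling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        t = random_tree(rng, [f"T{i}" for i in range(n)], with_lengths=False)
        m = random_matrix(rng, t.leaf_labels(), n_chars=3)
        assert fp.fitch_steps(t, m) == brute_fitch(t, m)

    def test_invariant_under_rerooting_and_leaf_permutation(self):
        rng = np.random.default_rng(77)
        t = random_tree(rng, list("ABCDEF"))
        m = random_matrix(rng, list("FEDCBA"), n_chars=5)  # permuted order
        base = fp.fitch_steps(t, m)
        for v in t.children:
            if t.children[v]:
                assert fp.fitch_steps(t.reroot_at(v), m) == base

    def test_missing_row_errors(self):
        t = fp.read_newick("((A,B),(C,D));")
        m = single_char_matrix({"A": 0, "B": 0, "C": 1}, 2)
        with pytest.raises(KeyError):
            fp.fitch_steps(t, m)


class TestAttachFossil:
    def test_counts_on_quartet(self):
        backbone = fp.read_newick("((A,B),(C,D));")
        internal = canonical_split({"C", "D"}, "ABCD")
        t = fp.attach_fossil(backbone, internal, "F")
        assert len(t.leaf_nodes()) == 5
        assert t.n_edges() == 7

    def test_remove_fossil_recovers_backbone(self):
        rng = np.random.default_rng(3)
        backbone = random_tree(rng, list("ABCDEFGH"))
        for edge in backbone.edge_splits():
            t = fp.attach_fossil(backbone, edge, "X")
            back = t.remove_leaf("X")
            assert tree_to_splits(back) == tree_to_splits(backbone)
            for e, x in backbone.edge_lengths().items():
                assert back.edge_lengths()[e] == pytest.approx(x)

    def test_all_attachments_pairwise_nonisomorphic(self):
        rng = np.random.default_rng(11)
        backbone = random_tree(rng, [f"T{i}" for i in range(10)])
        edges = list(backbone.edge_splits())
        assert len(edges) == 17
        split_sets = [tree_to_splits(fp.attach_fossil(backbone, e, "F"))
                      for e in edges]
        for i in range(len(edges)):
            for j in range(i + 1, len(edges)):
                assert split_sets[i] != split_sets[j]

    def test_existing_label_rejected(self):
        backbone = fp.read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fp.attach_fossil(backbone, canonical_split({"C", "D"}, "ABCD"), "A")


class TestPlacementProfile:
    def test_duplicate_row_places_on_that_terminal_edge(self):
        rng = np.random.default_rng(8)
        backbone = random_tree(rng, list("ABCDE"))
        m = random_matrix(rng, list("ABCDE"), n_chars=6, missing_p=0, poly_p=0)
        m = CharacterMatrix(taxa=TaxonSet(list("ABCDE") + ["F"]),
                            rows={**m.rows, "F": m.rows["C"]},
                            state_space=m.state_space)
        profile = fp.placement_profile(backbone, m, "F")
        c_edge = canonical_split({"C"}, "ABCDE")
        assert c_edge in profile.mp_edges
        # duplicating a taxon is free there
        extant = m.restrict_taxa(list("ABCDE"))
        assert profile.min_steps == fp.fitch_steps(backbone, extant)

    @pytest.mark.parametrize("seed", range(5))
    def test_per_edge_scores_match_rebuild_oracle(self, seed):
        rng = np.random.default_rng(40 + seed)
        backbone = random_tree(rng, list("ABCDE"))
        m = random_matrix(rng, list("ABCDE") + ["F"], n_chars=4)
        profile = fp.placement_profile(backbone, m, "F")
        assert len(profile.edge_steps) == 7  # 2L-3
        for edge, steps in profile.edge_steps.items():
            rebuilt = fp.attach_fossil(backbone, edge, "F")
            assert steps == brute_fitch(rebuilt, m)
        assert profile.min_steps == min(profile.edge_steps.values())
        assert profile.mp_edges == frozenset(
            e for e, s in profile.edge_steps.items() if s == profile.min_steps)

    def test_adding_taxon_never_reduces_steps(self):
        rng = np.random.default_rng(17)
        backbone = random_tree(rng, list("ABCDEF"))
        m = random_matrix(rng, list("ABCDEF") + ["X"], n_chars=8)
        profile = fp.placement_profile(backbone, m, "X")
        extant_steps = fp.fitch_steps(backbone, m.restrict_taxa(list("ABCDEF")))
        assert profile.min_steps >= extant_steps


class TestBootstrap:
    def test_unique_synapomorphy_gives_certain_placement(self):
        backbone = fp.read_newick("((A,B),(C,D));")
        taxa = TaxonSet(list("ABCDF"))
        rows = {t: tuple(frozenset([1]) if t in ("F", "C") else frozenset([0])
                         for _ in range(4)) for t in taxa}
        m = CharacterMatrix(taxa=taxa, rows=rows, state_space=(2,) * 4)
        boot = fp.bootstrap_placements(backbone, m, "F", n_replicates=25, seed=1)
        c_edge = canonical_split({"C"}, "ABCD")
        assert boot.placement_support[c_edge] == pytest.approx(1.0)

    def test_supports_normalized(self):
        rng = np.random.default_rng(5)
        backbone = random_tree(rng, list("ABCDE"))
        m = random_matrix(rng, list("ABCDE") + ["F"], n_chars=10)
        boot = fp.bootstrap_placements(backbone, m, "F", n_replicates=50, seed=2)
        assert all(0.0 <= v <= 1.0 for v in boot.placement_support.values())
        assert all(0.0 <= v <= 1.0 for v in boot.split_support.values())
        assert sum(boot.placement_support.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_straight_line_reference(self):
        """Replay the published resampling scheme with an independent Fitch
        oracle and per-replicate tallying."""
        rng = np.random.default_rng(13)
        backbone = random_tree(rng, list("ABCDE"))
        m = random_matrix(rng, list("ABCDE") + ["F"], n_chars=6)
        n_reps, seed = 10, 99
        boot = fp.bootstrap_placements(backbone, m, "F", n_reps, seed)

        edges = list(backbone.edge_splits())
        expected = {e: 0.0 for e in edges}
        for idx in bootstrap_replicate_indices(m.n_chars, n_reps, seed):
            rep = m.select_chars(list(idx))
            steps = {e: brute_fitch(fp.attach_fossil(backbone, e, "F"), rep)
                     for e in edges}
            lo = min(steps.values())
            mp = [e for e in edges if steps[e] == lo]
            for e in mp:
                expected[e] += 1.0 / (len(mp) * n_reps)
        for e in edges:
            assert boot.placement_support[e] == pytest.approx(expected[e], abs=1e-12)

    def test_replicate_count_validated(self):
        backbone = fp.read_newick("((A,B),(C,D));")
        m = random_matrix(np.random.default_rng(0), list("ABCDF"), n_chars=3)
        with pytest.raises(ValueError):
            fp.bootstrap_placements(backbone, m, "F", n_replicates=0, seed=1)
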