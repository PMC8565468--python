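"""Ancestral reconstruction, TSS, and TSS association tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from mitobias import simulate
from mitobias.ancestral import (
    BASES,
    fitch_parsimony,
    hky_rate_matrix,
    marginal_ml_states,
    site_log_likelihood,
    total_substitution_score,
    tss_frequency_association,
    tss_table,
)
from mitobias.trees import RootedTree
from mitobias.variants import MergedVariantTable

from conftest import site_columns


def brute_force_parsimony(column, tree) -> int:
    """Exhaustive minimum over all 4^(internal nodes) assignments."""
    leaf_idx = {}
    for v in tree.leaves:
        s = column[tree.name[v]]
        leaf_idx[v] = None if s is None else BASES.index(s)
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    free_leaves = [v for v in tree.leaves if leaf_idx[v] is None]
    best = 10 ** 9
    for combo in itertools.product(range(4), repeat=len(internal) + len(free_leaves)):
        assign = dict(zip(internal + free_leaves, combo))
        assign.update({v: s for v, s in leaf_idx.items() if s is not None})
        changes = sum(
            1 for v in range(tree.n_nodes)
            if v != tree.root and assign[v] != assign[tree.parent[v]]
        )
        best = min(best, changes)
    return best


def brute_force_log_likelihood(column, tree, kappa, pi) -> float:
    q = hky_rate_matrix(kappa, pi)
    pmat = {v: expm(q * tree.edge_length[v])
            for v in range(tree.n_nodes) if v != tree.root}
    leaf_idx = {v: BASES.index(column[tree.name[v]]) for v in tree.leaves}
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    total = 0.0
    for combo in itertools.product(range(4), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign.update(leaf_idx)
        lik = pi[assign[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                lik *= pmat[v][assign[tree.parent[v]], assign[v]]
        total += lik
    return float(np.log(total))


class TestFitch:
    @pytest.mark.parametrize(
        "newick,column,expected",
        [
            ("((a:1,b:1):1,c:1);", {"a": "A", "b": "A", "c": "G"}, 1),
            ("((a:1,b:1):1,c:1);", {"a": "A", "b": "A", "c": "A"}, 0),
            ("((a:1,b:1):1,(c:1,d:1):1);",
             {"a": "A", "b": "G", "c": "A", "d": "G"}, 2),
            ("(a:1,b:1,c:1,d:1);",  # star/multifurcation
             {"a": "A", "b": "C", "c": "G", "d": "T"}, 3),
        ],
    )
    def test_known_scores(self, newick, column, expected):
        tree = RootedTree.from_newick(newick)
        score, assignment = fitch_parsimony(column, tree)
        assert score == expected
        assert total_substitution_score(assignment, tree) == expected

    def test_missing_leaf_uses_full_state_set(self):
        tree = RootedTree.from_newick("((a:1,b:1):1,c:1);")
        score, _ = fitch_parsimony({"a": "A", "b": "A", "c": None}, tree)
        assert score == 0

    def test_absent_leaf_is_an_error(self):
        tree = RootedTree.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="c"):
            fitch_parsimony({"a": "A", "b": "A"}, tree)

    def test_alphabetical_tie_breaking(self):
        # two equally parsimonious root states; A must win
        tree = RootedTree.from_newick("(a:1,b:1);")
        _, assignment = fitch_parsimony({"a": "T", "b": "A"}, tree)
        assert assignment.states[tree.root] == "A"

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            tree = simulate.random_rooted_tree(n, rng)
            column = {
                name: (None if rng.random() < 0.1 else BASES[rng.integers(4)])
                for name in tree.leaf_names
            }
            score, assignment = fitch_parsimony(column, tree)
            assert score == brute_force_parsimony(column, tree)
            assert total_substitution_score(assignment, tree) == score


class TestMarginalML:
    def test_three_leaf_star_majority_root(self):
        tree = RootedTree.from_newick("(a:0.2,b:0.2,c:0.2);")
        a = marginal_ml_states({"a": "A", "b": "A", "c": "G"}, tree, kappa=1.0)
        assert a.states[tree.root] == "A"
        assert np.allclose(a.posteriors.sum(axis=1), 1.0)

    def test_short_branches_force_subtree_state(self):
        tree = RootedTree.from_newick("((a:1e-9,b:1e-9):1e-9,c:1.0);")
        a = marginal_ml_states({"a": "C", "b": "C", "c": "G"}, tree)
        internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
        # the cherry ancestor is pinned to C by its near-zero branches
        cherry = [v for v in internal if v != tree.root][0]
        assert a.states[cherry] == "C"
        assert a.posteriors[cherry, BASES.index("C")] > 0.999

    def test_observed_leaves_keep_observed_state(self):
        tree = RootedTree.from_newick("((a:0.5,b:0.5):0.5,c:0.5);")
        a = marginal_ml_states({"a": "T", "b": "C", "c": "G"}, tree)
        for v in tree.leaves:
            assert a.states[v] == {"a": "T", "b": "C", "c": "G"}[tree.name[v]]

    def test_likelihood_matches_brute_force(self):
        rng = np.random.default_rng(23)
        pi = np.array([0.31, 0.31, 0.13, 0.25])
        for _ in range(10):
            n = int(rng.integers(3, 6))
            tree = simulate.random_rooted_tree(n, rng, 0.3)
            column = {name: BASES[rng.integers(4)] for name in tree.leaf_names}
            ours = site_log_likelihood(column, tree, kappa=3.0,
                                       base_frequencies=pi)
            brute = brute_force_log_likelihood(column, tree, 3.0, pi)
            assert ours == pytest.approx(brute, rel=1e-9)

    def test_invalid_model_rejected(self):
        tree = RootedTree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            marginal_ml_states({"a": "A", "b": "A"}, tree, kappa=-1.0)
        with pytest.raises(ValueError):
            hky_rate_matrix(2.0, (0.5, 0.5, 0.5, 0.5))


class TestTSS:
    def test_identical_leaves_score_zero(self):
        tree = RootedTree.from_newick("((a:1,b:1):1,c:1);")
        _, a = fitch_parsimony({"a": "T", "b": "T", "c": "T"}, tree)
        assert total_substitution_score(a, tree) == 0

    def test_invariant_under_child_rotation(self):
        col = {"a": "A", "b": "G", "c": "C", "d": "T"}
        t1 = RootedTree.from_newick("((a:1,b:2):1,(c:1,d:1):2);")
        t2 = RootedTree.from_newick("((d:1,c:1):2,(b:2,a:1):1);")
        s1, a1 = fitch_parsimony(col, t1)
        s2, a2 = fitch_parsimony(col, t2)
        assert s1 == s2
        assert total_substitution_score(a1, t1) == total_substitution_score(a2, t2)

    def test_tss_bounded_by_true_event_count(self, evolution_run):
        tree, alignment, truth = evolution_run
        tss = tss_table(site_columns(alignment), tree)
        j = tss.merge(truth, on="site")
        assert (j["tss"] <= j["true_events"]).all()

    def test_ml_and_fitch_paths_both_run(self, evolution_run):
        tree, alignment, _ = evolution_run
        cols = site_columns(alignment).head(30)
        fitch = tss_table(cols, tree, method="fitch")
        ml = tss_table(cols, tree, method="ml", kappa=4.0)
        assert (fitch["method"] == "fitch").all()
        assert (ml["method"] == "ml").all()
        assert len(fitch) == len(ml) == 30


class TestTssFrequencyAssociation:
    @staticmethod
    def _merged_for(tss_df, counts_by_class):
        """Build a minimal merged table whose synonymous P3 rows hit tss sites."""
        rows = []
        classes = list(counts_by_class)
        for i, site in enumerate(tss_df.itertuples()):
            fc = classes[i % len(classes)]
            rows.append(
                {
                    "position": i + 1, "ref_base": "A", "alt_base": "G",
                    "gene": site.gene, "codon_index": site.codon_index,
                    "codon_position": 3, "ref_codon": "GGA", "alt_codon": "GGG",
                    "ref_aa": "Gly", "alt_aa": "Gly", "is_synonymous": True,
                    "sub_type": "transition", "counts_hom": counts_by_class[fc],
                    "counts_het": 0, "total_count": counts_by_class[fc],
                    "frequency_class": fc, "is_ssne": counts_by_class[fc] == 0,
                }
            )
        return MergedVariantTable(table=pd.DataFrame(rows), n_samples=100000)

    @staticmethod
    def _tss_df(values):
        return pd.DataFrame(
            {
                "gene": "G1",
                "codon_index": np.arange(1, len(values) + 1),
                "amino_acid": "Gly",
                "trna_family": "G",
                "degeneracy_class": "fourfold",
                "tss": values,
                "method": "fitch",
            }
        )

    def test_equal_tss_gives_zero_d_and_capped_p(self):
        tss_df = self._tss_df([5] * 40)
        merged = self._merged_for(tss_df, {"absent": 0, "ultra_rare": 3})
        out = tss_frequency_association(tss_df, merged)
        done = out[~out["skipped"]]
        assert len(done) == 1
        assert (done["d"] == 0).all()
        assert (done["p_corrected"] == 1.0).all()

    def test_common_class_excluded_from_testing(self):
        tss_df = self._tss_df(list(range(60)))
        merged = self._merged_for(
            tss_df, {"absent": 0, "ultra_rare": 3, "common": 90000}
        )
        out = tss_frequency_association(tss_df, merged)
        assert not (
            (out["group_a"] == "common") | (out["group_b"] == "common")
        ).any()

    def test_small_groups_skipped_with_notice(self):
        tss_df = self._tss_df([1, 2, 3])
        merged = self._merged_for(tss_df, {"absent": 0, "ultra_rare": 3})
        # 3 sites split 2/1: the singleton group cannot be tested
        out = tss_frequency_association(tss_df, merged)
        assert out["skipped"].any()
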