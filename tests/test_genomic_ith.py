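import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ithseq.genomic_ith import (
    build_parsimony_tree, classify_trunk_branch_private, cluster_clonal_architecture,
    estimate_ccf, infer_multiplicity, merge_regions, mutation_matrix,
    mutational_jaccard, trunk_fraction,
)

# ---------------------------------------------------------------------------
# independent brute-force parsimony oracle (own topology enumeration and
# exhaustive internal-state assignment, no Sankoff)


def _oracle_topologies(leaves):
    if len(leaves) == 1:
        yield ("leaf", leaves[0])
        return
    for split in range(1, 2 ** (len(leaves) - 1)):
        left = [l for i, l in enumerate(leaves) if split >> i & 1]
        right = [l for l in leaves if l not in left]
        if not left or not right:
            continue
        for lt in _oracle_topologies(left):
            for rt in _oracle_topologies(right):
                yield ("node", lt, rt)


def _oracle_internal_nodes(tree, acc):
    if tree[0] == "node":
        acc.append(tree)
        _oracle_internal_nodes(tree[1], acc)
        _oracle_internal_nodes(tree[2], acc)
    return acc


def _oracle_changes(tree, states, assignment, parent_state):
    s = states[tree[1]] if tree[0] == "leaf" else assignment[id(tree)]
    n = int(s != parent_state)
    if tree[0] == "node":
        n += _oracle_changes(tree[1], states, assignment, s)
        n += _oracle_changes(tree[2], states, assignment, s)
    return n


def oracle_min_length(matrix: pd.DataFrame) -> int:
    """Exhaustive minimum parsimony length with an all-zero root."""
    leaves = list(matrix.columns)
    best = None
    for topo in _oracle_topologies(leaves):
        total = 0
        internals = _oracle_internal_nodes(topo, [])
        for _, row in matrix.iterrows():
            states = dict(row)
            char_best = None
            for combo in itertools.product((0, 1), repeat=len(internals)):
                assignment = {id(n): s for n, s in zip(internals, combo)}
                c = _oracle_changes(topo, states, assignment, 0)
                char_best = c if char_best is None else min(char_best, c)
            total += char_best
        best = total if best is None else min(best, total)
    return best


class TestTrunkBranchPrivate:
    def test_three_region_labels(self):
        mat = pd.DataFrame({"R1": [1, 1, 0], "R2": [1, 1, 0], "R3": [1, 0, 1]},
                           index=["t", "b", "p"])
        lab = classify_trunk_branch_private(mat)["label"]
        assert lab.tolist() == ["trunk", "branch", "private"]

    def test_trunk_fraction_counts_all_ones_rows(self):
        mat = pd.DataFrame(np.ones((8, 3), dtype=int), columns=list("ABC"))
        extra = pd.DataFrame([[1, 0, 0], [0, 1, 0]], columns=list("ABC"))
        assert trunk_fraction(pd.concat([mat, extra])) == pytest.approx(0.8)

    def test_single_region_all_trunk_and_flagged(self):
        mat = pd.DataFrame({"R1": [1, 1]})
        lab = classify_trunk_branch_private(mat)
        assert (lab["label"] == "trunk").all() and lab["excluded_from_ith"].all()

    def test_matrix_from_variant_table(self):
        variants = pd.DataFrame({
            "region_id": ["R1", "R2", "R1"], "chrom": ["chr1"] * 3,
            "pos": [5, 5, 9], "ref": ["C"] * 3, "alt": ["T"] * 3,
        })
        mat = mutation_matrix(variants, ["R1", "R2"])
        assert mat.loc["chr1:5:C>T"].tolist() == [1, 1]
        assert mat.loc["chr1:9:C>T"].tolist() == [1, 0]


class TestJaccard:
    def test_hand_value(self):
        mat = pd.DataFrame({"A": [1, 1, 1, 0], "B": [0, 1, 1, 1]},
                           index=["a", "b", "c", "d"])
        df, mean = mutational_jaccard(mat)
        assert mean == pytest.approx(0.5)

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_bounded_and_identity(self, abits, bbits):
        rows = [(abits >> i & 1, bbits >> i & 1) for i in range(12)]
        rows = [r for r in rows if any(r)]
        if not rows:
            return
        mat = pd.DataFrame(rows, columns=["A", "B"])
        _, ji = mutational_jaccard(mat)
        _, ji_swapped = mutational_jaccard(mat[["B", "A"]])
        assert ji == pytest.approx(ji_swapped)
        assert 0 <= ji <= 1
        if (mat["A"] == mat["B"]).all():
            assert ji == 1.0


class TestParsimony:
    def test_perfect_phylogeny_length_equals_mutation_count(self):
        mat = pd.DataFrame({"R1": [1, 1, 0, 0], "R2": [1, 0, 1, 0], "R3": [1, 0, 0, 1]})
        tree = build_parsimony_tree(mat)
        assert tree.total_length == 4
        assert tree.trunk_count == 1

    def test_trunk_only_matrix_puts_everything_on_trunk(self):
        mat = pd.DataFrame(np.ones((7, 3), dtype=int), columns=["R1", "R2", "R3"])
        tree = build_parsimony_tree(mat)
        assert tree.trunk_count == tree.total_length == 7

    def test_homoplasy_matrix_matches_oracle(self):
        mat = pd.DataFrame({"R1": [1, 1, 1, 1], "R2": [1, 1, 0, 0], "R3": [1, 0, 1, 0]})
        tree = build_parsimony_tree(mat)
        assert tree.total_length == oracle_min_length(mat)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_regions = int(rng.integers(2, 5))
            n_mut = int(rng.integers(1, 9))
            mat = pd.DataFrame(
                rng.integers(0, 2, size=(n_mut, n_regions)),
                columns=[f"R{i}" for i in range(n_regions)])
            mat = mat[mat.sum(axis=1) > 0]
            if not len(mat):
                continue
            assert build_parsimony_tree(mat).total_length == oracle_min_length(mat)

    def test_trunk_fraction_identity_on_homoplasy_free_matrix(self):
        """Trunk-edge share of tree length equals the trunk label fraction."""
        mat = pd.DataFrame({"R1": [1, 1, 1, 0, 0], "R2": [1, 1, 0, 1, 0],
                            "R3": [1, 1, 0, 0, 1]})
        tree = build_parsimony_tree(mat)
        assert tree.trunk_fraction == pytest.approx(trunk_fraction(mat))

    def test_region_bound_enforced(self):
        mat = pd.DataFrame(np.ones((2, 9), dtype=int),
                           columns=[f"R{i}" for i in range(9)])
        with pytest.raises(ValueError, match="exhaustive"):
            build_parsimony_tree(mat)

    def test_newick_contains_all_regions(self):
        mat = pd.DataFrame({"R1": [1, 0], "R2": [1, 1], "R3": [0, 1]})
        nwk = build_parsimony_tree(mat).newick()
        assert all(r in nwk for r in ("germline", "R1", "R2", "R3"))


class TestCcf:
    @pytest.mark.parametrize("vaf,purity,cn,mult,expected", [
        (0.5, 1.0, 2, 1, 1.0),
        (0.25, 0.5, 2, 1, 1.0),  # vaf*(1+1)/0.5 = 1.0 algebraically
        (0.0, 0.8, 2, 1, 0.0),
    ])
    def test_formula(self, vaf, purity, cn, mult, expected):
        ccf, raw = estimate_ccf(vaf, purity, cn, mult)
        assert ccf == pytest.approx(expected)

    def test_raw_value_recorded_before_clamp(self):
        ccf, raw = estimate_ccf(0.9, 0.5, 2, 1)
        assert ccf == 1.0 and raw == pytest.approx(3.6)

    def test_zero_purity_errors(self):
        with pytest.raises(ValueError):
            estimate_ccf(0.5, 0.0)

    def test_multiplicity_rule(self):
        assert infer_multiplicity(0.9, 0.5, 4, a_count=3) == 3
        assert infer_multiplicity(0.2, 0.5, 2, a_count=2) == 1
        assert infer_multiplicity(0.9, 0.5, 4, a_count=1) == 1


class TestMergeRegions:
    def test_counts_sum_across_regions(self):
        v = pd.DataFrame({
            "patient_id": ["P", "P"], "region_id": ["R1", "R2"],
            "chrom": ["chr1"] * 2, "pos": [10, 10], "ref": ["C"] * 2,
            "alt": ["T"] * 2, "t_alt": [10, 30], "t_depth": [100, 100],
            "lod": [20.0, 35.0],
        })
        m = merge_regions(v)
        assert len(m) == 1
        assert m.iloc[0]["t_vaf"] == pytest.approx(0.2)
        assert m.iloc[0]["lod"] == 35.0


class TestClonalArchitecture:
    def test_tight_single_cluster(self):
        rng = np.random.default_rng(0)
        ccf = 1.0 + rng.normal(0, 0.01, 40)
        arch = cluster_clonal_architecture(ccf)
        assert arch.k == 1 and arch.clonal_fraction == 1.0

    def test_two_population_recovery(self):
        rng = np.random.default_rng(3)
        d = 180
        raw = np.concatenate([
            rng.binomial(d, 0.5, 100) / d * 2,   # clonal, ccf 1 at purity 1 / CN 2
            rng.binomial(d, 0.2, 50) / d * 2,    # subclone at ccf 0.4
        ])
        arch = cluster_clonal_architecture(raw)
        assert arch.clonal_fraction == pytest.approx(2 / 3, abs=0.05)

    def test_too_few_mutations_flagged_fallback(self):
        arch = cluster_clonal_architecture(np.array([0.9, 0.5, 0.2]))
        assert arch.fallback and arch.k == 1

    def test_clonal_iff_highest_prevalence_cluster(self):
        rng = np.random.default_rng(1)
        raw = np.concatenate([rng.normal(1.0, 0.03, 30), rng.normal(0.3, 0.03, 30)])
        arch = cluster_clonal_architecture(raw)
        top = arch.assignments[arch.assignments["clonal"]]
        rest = arch.assignments[~arch.assignments["clonal"]]
        assert top["ccf"].mean() > rest["ccf"].mean()
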