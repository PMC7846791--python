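import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from frontassembly.assembly import (
    Process,
    bmntd,
    bnti,
    classify_process,
    cophenetic_distances,
    jaccard_dissimilarity,
    mantel,
    process_summary,
    raup_crick,
    AssemblyResult,
)
from frontassembly.core import ValidationError
from frontassembly.synthetic import generate_tree

from conftest import make_table


def brute_force_bmntd(a, b, dm: DistanceMatrix) -> float:
    """Independent double-loop oracle for βMNTD."""
    d = {}
    for i in dm.ids:
        for j in dm.ids:
            d[i, j] = dm[i, j]
    mean_a = np.mean([min(d[i, j] for j in b) for i in a])
    mean_b = np.mean([min(d[i, j] for i in a) for j in b])
    return 0.5 * (mean_a + mean_b)


class TestCophenetic:
    def test_four_tip_path_sums(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["C", "D"] == pytest.approx(2.0)
        assert dm["A", "A"] == 0.0

    def test_star_tree_all_equal(self):
        tree = TreeNode.read(io.StringIO("(A:3,B:3,C:3,D:3);"))
        dm = cophenetic_distances(tree)
        off = dm.data[np.triu_indices(4, 1)]
        assert np.allclose(off, 6.0)

    def test_ultrametric_max_is_twice_depth(self):
        tree = generate_tree(32, seed=5)
        depth = next(tree.tips()).accumulate_to_ancestor(tree)
        dm = cophenetic_distances(tree)
        assert dm.data.max() <= 2 * depth + 1e-9


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_dissimilarity({"A", "B"}, {"A", "B"}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_dissimilarity({"A"}, {"B"}) == 1.0

    def test_partial_overlap(self):
        assert jaccard_dissimilarity({"A", "B"}, {"B", "C"}) == pytest.approx(2 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_dissimilarity(set(), {"A"})


class TestBmntd:
    def test_equal_communities_are_zero(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        assert bmntd({"A", "B"}, {"A", "B"}, dm) == 0.0

    def test_disjoint_clades(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        assert bmntd({"A", "B"}, {"C", "D"}, dm) == pytest.approx(4.0)

    def test_nested_communities(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        # 0.5 * (0 + (0 + 4)/2) = 1.0
        assert bmntd({"A"}, {"A", "C"}, dm) == pytest.approx(1.0)

    def test_symmetry_and_shared_taxon_monotonicity(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        a, b = {"A", "B"}, {"C", "D"}
        assert bmntd(a, b, dm) == bmntd(b, a, dm)
        # adding a shared taxon never increases βMNTD
        assert bmntd(a | {"D"}, b | {"D"}, dm) <= bmntd(a, b, dm)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5, 33))
            tree = generate_tree(n, seed=int(rng.integers(1, 10**6)))
            dm = cophenetic_distances(tree)
            tips = list(dm.ids)
            a = set(rng.choice(tips, size=int(rng.integers(1, n)), replace=False))
            b = set(rng.choice(tips, size=int(rng.integers(1, n)), replace=False))
            assert bmntd(a, b, dm) == pytest.approx(
                brute_force_bmntd(a, b, dm), abs=1e-12
            )

    def test_unknown_taxon_rejected(self, four_tip_tree):
        dm = cophenetic_distances(four_tip_tree)
        with pytest.raises(ValidationError):
            bmntd({"A"}, {"Z"}, dm)


class TestBnti:
    def test_star_tree_gives_zero(self):
        # every shuffle leaves distances unchanged -> sd = 0 -> βNTI := 0
        otus = [f"t{i}" for i in range(6)]
        tree = TreeNode.read(io.StringIO("(" + ",".join(f"{o}:2" for o in otus) + ");"))
        table = make_table({
            "s1": {o: 1 for o in otus[:3]},
            "s2": {o: 1 for o in otus[3:]},
        })
        z = bnti(table, tree, n_null=49, seed=0)
        assert np.allclose(z.to_numpy(), 0.0)

    def test_seeded_bit_reproducibility(self):
        from frontassembly.synthetic import generate_metacommunity, scenario_preset

        table, tree, *_ = generate_metacommunity(scenario_preset("drift", seed=3))
        z1 = bnti(table, tree, n_null=49, seed=11)
        z2 = bnti(table, tree, n_null=49, seed=11)
        assert np.array_equal(z1.to_numpy(), z2.to_numpy())

    def test_too_few_nulls_rejected(self, four_tip_tree):
        table = make_table({"s1": {"A": 1}, "s2": {"B": 1}})
        with pytest.raises(ValidationError):
            bnti(table, four_tip_tree, n_null=1, seed=0)

    def test_missing_tree_otu_errors_or_prunes(self, four_tip_tree):
        table = make_table({"s1": {"A": 1, "Z": 2}, "s2": {"B": 1, "C": 1}})
        with pytest.raises(ValidationError, match="Z"):
            bnti(table, four_tip_tree, n_null=9, seed=0)
        with pytest.warns(UserWarning, match="pruning"):
            z = bnti(table, four_tip_tree, n_null=9, seed=0,
                     missing_otus="prune")
        assert list(z.index) == ["s1", "s2"]

    def test_pairwise_pool_variant_runs_and_is_symmetric(self):
        from frontassembly.synthetic import generate_metacommunity, scenario_preset

        table, tree, *_ = generate_metacommunity(
            scenario_preset("drift", seed=4, n_otus=32, replicates=1,
                            community_size=300)
        )
        z = bnti(table, tree, n_null=29, seed=2, pool="pairwise")
        arr = z.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)


def enumerate_raup_crick(presence_a, presence_b, pool_weights: dict) -> float:
    """Exact RC by enumerating weighted sampling without replacement."""
    pool = sorted(pool_weights)
    ra, rb = len(presence_a), len(presence_b)
    j_obs = jaccard_dissimilarity(presence_a, presence_b)

    def subset_probs(k):
        probs = {}
        for perm in itertools.permutations(pool, k):
            p, remaining = 1.0, sum(pool_weights.values())
            for sp in perm:
                p *= pool_weights[sp] / remaining
                remaining -= pool_weights[sp]
            key = frozenset(perm)
            probs[key] = probs.get(key, 0.0) + p
        return probs

    pa, pb = subset_probs(ra), subset_probs(rb)
    below = ties = 0.0
    for sa, wa in pa.items():
        for sb, wb in pb.items():
            j = jaccard_dissimilarity(sa, sb)
            if j < j_obs - 1e-12:
                below += wa * wb
            elif abs(j - j_obs) <= 1e-12:
                ties += wa * wb
    return 2.0 * (below + 0.5 * ties) - 1.0


class TestRaupCrick:
    def test_two_species_exact_value(self):
        # pool {X, Y} at equal occupancy; A={X}, B={Y}:
        # exact RC = 2*(0.5 + 0.5*0.5) - 1 = 0.5
        table = make_table({"a": {"X": 1, "Y": 0}, "b": {"X": 0, "Y": 1}})
        rc = raup_crick(table, n_null=99999, seed=1)
        assert rc.loc["a", "b"] == pytest.approx(0.5, abs=0.02)
        exact = enumerate_raup_crick({"X"}, {"Y"}, {"X": 0.5, "Y": 0.5})
        assert exact == pytest.approx(0.5, abs=1e-12)

    def test_full_pool_pair_is_zero(self):
        table = make_table({"a": {"X": 2, "Y": 1}, "b": {"X": 1, "Y": 3}})
        rc = raup_crick(table, n_null=999, seed=0)
        assert rc.loc["a", "b"] == 0.0  # all nulls tie at J = 0

    def test_invariant_to_otu_relabelling(self):
        counts = {
            "a": {"o1": 1, "o2": 1, "o3": 0, "o4": 2},
            "b": {"o1": 0, "o2": 1, "o3": 2, "o4": 0},
            "c": {"o1": 3, "o2": 0, "o3": 1, "o4": 1},
        }
        t1 = make_table(counts)
        renamed = {
            s: {f"x_{o}": v for o, v in row.items()} for s, row in counts.items()
        }
        t2 = make_table(renamed)
        rc1 = raup_crick(t1, n_null=999, seed=5)
        rc2 = raup_crick(t2, n_null=999, seed=5)
        assert np.array_equal(rc1.to_numpy(), rc2.to_numpy())

    def test_monte_carlo_matches_enumeration_small_pools(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n_pool = int(rng.integers(3, 7))
            pool = [f"p{i}" for i in range(n_pool)]
            S = 4
            pres = (rng.random((S, n_pool)) < 0.6)
            for s in range(S):  # no empty communities
                if not pres[s].any():
                    pres[s, rng.integers(n_pool)] = True
            for j in range(n_pool):  # every species occupies >= 1 sample
                if not pres[:, j].any():
                    pres[rng.integers(S), j] = True
            table = make_table({
                f"s{s}": {pool[j]: int(pres[s, j]) for j in range(n_pool)}
                for s in range(S)
            })
            occ = {pool[j]: pres[:, j].mean() for j in range(n_pool)}
            rc = raup_crick(table, n_null=9999, seed=trial)
            sets = [frozenset(p for p in pool if pres[s, pool.index(p)])
                    for s in range(S)]
            for a, b in [(0, 1), (2, 3)]:
                exact = enumerate_raup_crick(sets[a], sets[b], occ)
                assert rc.iloc[a, b] == pytest.approx(exact, abs=0.05)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (-3.1, 0.2, Process.HOMOGENEOUS_SELECTION),
            (2.5, -0.3, Process.VARIABLE_SELECTION),
            (0.5, 0.97, Process.DISPERSAL_LIMITATION),
            (1.0, -0.99, Process.HOMOGENIZING_DISPERSAL),
            (0.0, 0.0, Process.DRIFT),
            # boundaries fall to the weaker category
            (-2.0, 0.0, Process.DRIFT),
            (2.0, 0.0, Process.DRIFT),
            (0.0, 0.95, Process.DRIFT),
            (0.0, -0.95, Process.DRIFT),
            (-2.0, 0.99, Process.DISPERSAL_LIMITATION),
            (2.0, -0.99, Process.HOMOGENIZING_DISPERSAL),
        ],
    )
    def test_rule_table(self, z, rc, expected):
        assert classify_process(z, rc) is expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            classify_process(math.nan, 0.0)
        with pytest.raises(ValidationError):
            classify_process(0.0, 1.5)


class TestProcessSummary:
    def _result(self, a, b, process):
        return AssemblyResult(a, b, 1.0, 1.0, 0.1, 0.0, 0.0, process, 99)

    def test_counts_and_edges(self):
        res = [
            self._result("s1", "s2", Process.HOMOGENEOUS_SELECTION),
            self._result("s1", "s3", Process.HOMOGENEOUS_SELECTION),
            self._result("s2", "s3", Process.DISPERSAL_LIMITATION),
        ]
        summary = process_summary(res)
        assert summary.counts["HomogeneousSelection"] == 2
        assert summary.counts["DispersalLimitation"] == 1
        assert len(summary.edges) == 1

    def test_all_selection_gives_empty_edge_list(self):
        res = [self._result("a", "b", Process.HOMOGENEOUS_SELECTION)]
        assert len(process_summary(res).edges) == 0

    def test_repeated_node_pair_accumulates_multiplicity(self):
        node_map = pd.Series({"r1": "F|July", "r2": "F|July", "c1": "C1|July"})
        res = [
            self._result("r1", "c1", Process.DISPERSAL_LIMITATION),
            self._result("r2", "c1", Process.DISPERSAL_LIMITATION),
        ]
        edges = process_summary(res, node_map).edges
        assert len(edges) == 1
        assert edges["multiplicity"].iloc[0] == 2


class TestMantel:
    def _random_dm(self, rng, n, ids):
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=ids)

    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        ids = [f"t{i}" for i in range(10)]
        dm = self._random_dm(rng, 10, ids)
        dm2 = DistanceMatrix(2.0 * dm.data, ids=ids)
        r, p = mantel(dm, dm2, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_exhaustive_enumeration_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        ids = list("abcde")
        dx = self._random_dm(rng, 5, ids)
        dy = self._random_dm(rng, 5, ids)
        iu = np.triu_indices(5, 1)
        x = dx.data[iu]
        r_obs = np.corrcoef(x, dy.data[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(5)))
        for p in perms:
            yp = dy.data[np.ix_(p, p)][iu]
            if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
                count += 1
        exact = count / len(perms)
        _, p_mc = mantel(dx, dy, n_perm=9999, seed=0)
        assert p_mc == pytest.approx(exact, abs=0.02)

    def test_constant_matrix_rejected(self):
        ids = list("abc")
        flat = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=ids)
        with pytest.raises(ValidationError):
            mantel(flat, flat, n_perm=9, seed=0)
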