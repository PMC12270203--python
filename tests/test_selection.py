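import dataclasses
import itertools

import numpy as np
import pytest
from Bio import Phylo
from io import StringIO

import pepgan as pg
from pepgan.selection import Ellipse, confidence_ellipse, ellipses_overlap


def brute_force_upgma(dist, ids):
    """Independent UPGMA oracle: clusters as frozensets, average distances
    recomputed from the original matrix at every step."""
    clusters = {frozenset([i]): 0.0 for i in range(len(ids))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=sorted), 2):
            d = np.mean([dist[i, j] for i in a for j in b])
            lo, hi = sorted((min(ids[i] for i in a), min(ids[i] for i in b)))
            key = (d, lo, hi)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merged = a | b
        del clusters[a], clusters[b]
        clusters[merged] = d / 2.0
        merges.append((frozenset(ids[i] for i in merged), d / 2.0))
    return merges


def tree_merge_heights(tree):
    return {frozenset(n.leaves()): n.height for n in tree.internal_nodes()}


class TestHamming:
    def test_identity_and_printed_pair(self):
        d = pg.hamming_matrix(["AAGIGILTV", "AAICTLLYD"])
        assert d[0, 0] == 0
        assert d[0, 1] == 6

    def test_metric_properties(self, rng):
        aas = np.array(list(pg.AMINO_ACIDS))
        seqs = ["".join(rng.choice(aas, 9)) for _ in range(8)]
        d = pg.hamming_matrix(seqs)
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, k] <= d[i, j] + d[j, k]

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            pg.hamming_matrix(["AAA", "AAAA"])


class TestUPGMA:
    def test_two_leaves(self):
        tree = pg.upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
        assert tree.height == 2.0
        assert sorted(tree.root.leaves()) == ["a", "b"]

    def test_three_leaf_hand_example(self):
        d = np.array([[0.0, 2, 4], [2, 0.0, 4], [4, 4, 0.0]])
        tree = pg.upgma(d, ["A", "B", "C"])
        heights = tree_merge_heights(tree)
        assert heights[frozenset({"A", "B"})] == 1.0
        assert heights[frozenset({"A", "B", "C"})] == 2.0

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 7))
            x = rng.integers(0, 5, size=(n, 9))
            d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
            ids = [f"t{trial}_{i}" for i in range(n)]
            ours = tree_merge_heights(pg.upgma(d, ids))
            oracle = dict(brute_force_upgma(d, ids))
            assert set(ours) == set(oracle)  # identical topology
            for clade, h in oracle.items():
                assert ours[clade] == pytest.approx(h)

    def test_ultrametric(self, rng):
        x = rng.integers(0, 4, size=(10, 9))
        d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
        tree = pg.upgma(d)
        # leaf depth from root is the root height for every leaf
        def depth(node, acc):
            if node.is_leaf:
                yield acc
            else:
                yield from depth(node.left, acc + (node.height - node.left.height))
                yield from depth(node.right, acc + (node.height - node.right.height))
        depths = list(depth(tree.root, 0.0))
        assert np.allclose(depths, tree.height)

    def test_newick_parses(self):
        d = np.array([[0.0, 2, 4], [2, 0.0, 4], [4, 4, 0.0]])
        tree = pg.upgma(d, ["A", "B", "C"])
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A", "B", "C"]


class TestBootstrap:
    def test_separated_groups_full_support(self):
        seqs = ["AAAAAAAAA"] * 3 + ["CCCCCCCCC"] * 3
        ids = [f"a{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
        tree = pg.bootstrap_support(seqs, ids, replicates=20, seed=1)
        supports = {frozenset(n.leaves()): n.support for n in tree.internal_nodes()}
        assert supports[frozenset(ids[:3])] == 100.0
        assert supports[frozenset(ids[3:])] == 100.0
        assert all(0 <= s <= 100 for s in supports.values())

    def test_seed_reproducibility(self):
        seqs = ["AAGIGILTV", "AAGIGILTA", "CCGIGILTV", "CCGIGILTA"]
        a = pg.bootstrap_support(seqs, replicates=10, seed=3)
        b = pg.bootstrap_support(seqs, replicates=10, seed=3)
        assert {frozenset(n.leaves()): n.support for n in a.internal_nodes()} == \
               {frozenset(n.leaves()): n.support for n in b.internal_nodes()}


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        d = np.array([[0.0, 2, 4], [2, 0.0, 4], [4, 4, 0.0]])
        return pg.upgma(d, ["A", "B", "C"])

    def test_above_root_single_clade(self, tree):
        assert pg.cut_tree(tree, height=10.0) == [["A", "B", "C"]]

    def test_zero_gives_singletons(self, tree):
        assert pg.cut_tree(tree, height=0.0) == [["A"], ["B"], ["C"]]

    def test_intermediate_cut(self, tree):
        assert pg.cut_tree(tree, height=1.5) == [["A", "B"], ["C"]]

    def test_negative_rejected(self, tree):
        with pytest.raises(ValueError):
            pg.cut_tree(tree, height=-1.0)


class TestCladeSimilarity:
    def test_within_and_across(self):
        seqs = ["AAAAAAAAA", "AAAAAAAAA", "CCCCCCCCC", "CCCCCCCCC"]
        ids = ["a1", "a2", "c1", "c2"]
        d = pg.hamming_matrix(seqs)
        out = pg.clade_similarity([["a1", "a2"], ["c1", "c2"]], d, ids)
        assert out["within"].tolist() == [0.0, 0.0]
        assert out["across"].tolist() == [9.0, 9.0]

    def test_matches_pair_enumeration(self, rng):
        aas = np.array(list(pg.AMINO_ACIDS))
        seqs = ["".join(rng.choice(aas, 9)) for _ in range(4)]
        ids = ["p0", "p1", "p2", "p3"]
        d = pg.hamming_matrix(seqs)
        out = pg.clade_similarity([["p0", "p1", "p2"], ["p3"]], d, ids)
        assert out.loc[0, "within"] == pytest.approx((d[0, 1] + d[0, 2] + d[1, 2]) / 3)
        assert out.loc[0, "across"] == pytest.approx((d[0, 3] + d[1, 3] + d[2, 3]) / 3)
        assert np.isnan(out.loc[1, "within"])


class TestMDS:
    def test_exact_recovery_of_planar_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = pg.mds_embed(d, dims=2)
        # Procrustes: compare centered distance matrices instead of raw coords
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)

    def test_collinear_points_have_flat_second_axis(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = pg.mds_embed(d, dims=2)
        assert np.allclose(coords[:, 1], 0.0, atol=1e-6)

    def test_matches_scikit_bio_pcoa(self, rng):
        from skbio.stats.ordination import pcoa

        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = pg.mds_embed(d, dims=2)
        ref = pcoa(d, number_of_dimensions=2).samples.to_numpy()
        for k in range(2):
            assert np.allclose(np.abs(ours[:, k]), np.abs(ref[:, k]), atol=1e-8)

    def test_feature_matrix_input(self, rng):
        x = rng.normal(size=(8, 5))
        coords = pg.mds_embed(x, dims=2)
        assert coords.shape == (8, 2)


class TestEllipses:
    def test_identical_clouds_overlap(self, rng):
        pts = rng.normal(size=(30, 2))
        assert pg.ellipses_overlap(confidence_ellipse(pts), confidence_ellipse(pts))

    def test_distant_clouds_do_not_overlap(self, rng):
        a = confidence_ellipse(rng.normal(0, 1, size=(30, 2)))
        b = confidence_ellipse(rng.normal(100, 1, size=(30, 2)))
        assert not pg.ellipses_overlap(a, b)

    def test_touching_circles_overlap(self):
        # unit-covariance ellipses have radius sqrt(chi2_95); centers exactly
        # two radii apart touch at one boundary point
        from pepgan.selection import CHI2_95_DF2

        r = np.sqrt(CHI2_95_DF2)
        a = Ellipse(mean=np.zeros(2), cov=np.eye(2))
        b = Ellipse(mean=np.array([2 * r, 0.0]), cov=np.eye(2))
        assert pg.ellipses_overlap(a, b)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="singular"):
            confidence_ellipse(pts)


class TestPAM:
    def test_singleton(self):
        d = np.zeros((1, 1))
        assert pg.pam_medoid(d, ["only"], ["only"]) == "only"

    def test_line_example(self):
        d = np.abs(np.array([0.0, 1.0, 10.0])[:, None] - np.array([0.0, 1.0, 10.0])[None, :])
        assert pg.pam_medoid(d, ["a", "b", "c"], ["a", "b", "c"]) == "b"

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            pts = rng.normal(size=(n, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            ids = [f"m{i}" for i in range(n)]
            costs = {ids[i]: d[i].sum() for i in range(n)}
            oracle = min(ids, key=lambda m: (costs[m], m))
            assert pg.pam_medoid(d, ids, ids) == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pg.pam_medoid(np.zeros((1, 1)), [], ["a"])


class TestSelectLibrary:
    def _planted(self, seed=5):
        ds, truth, founders = pg.planted_clade_dataset(
            n_clades=4, clade_size=10, mutations_per_member=1, seed=seed
        )
        real = pg.PeptideDataset(
            [r for r in ds if "_m" in r.id and int(r.id.split("_m")[1]) < 7]
        )
        gen = pg.PeptideDataset(
            [dataclasses.replace(r, source="generated")
             for r in ds if "founder" in r.id or ("_m" in r.id and int(r.id.split("_m")[1]) >= 7)]
        )
        return real, gen, founders

    def test_planted_founders_selected(self):
        real, gen, founders = self._planted()
        lib = pg.select_library(real, gen, cut_height=2.5)
        assert sorted(lib.sequences) == sorted(founders)
        assert all(r in gen.ids for r in lib.representatives)

    def test_relabeled_identical_sets_all_overlap(self, rng):
        aas = np.array(list(pg.AMINO_ACIDS))
        seqs = ["".join(rng.choice(aas, 9)) for _ in range(12)]
        real = pg.dataset_from_sequences(seqs, prefix="r")
        gen = pg.dataset_from_sequences(seqs, prefix="g", source="generated")
        lib = pg.select_library(real, gen, cut_height=10.0)  # one clade
        assert lib.table["overlap"].all()
        assert len(lib.representatives) == len(lib.clades)

    def test_distant_generated_yields_empty_library(self):
        real = pg.dataset_from_sequences(
            ["AAAAAAAA" + c for c in "ACDEFG"], prefix="r"
        )
        gen = pg.dataset_from_sequences(
            ["WWWWWWWW" + c for c in "ACDEFG"], prefix="g", source="generated"
        )
        lib = pg.select_library(real, gen, cut_height=1.5)
        assert lib.representatives == []

    def test_output_bounded_by_clades_and_provenance(self):
        real, gen, _ = self._planted(seed=9)
        lib = pg.select_library(real, gen, cut_height=2.5)
        assert len(lib.representatives) <= len(lib.clades)
        gen_ids = set(gen.ids)
        assert all(r in gen_ids for r in lib.representatives)

    def test_overlapping_ids_rejected(self):
        real = pg.dataset_from_sequences(["AAGIGILTV"] * 2, prefix="x")
        gen = pg.dataset_from_sequences(["FLIDLAFLI"] * 2, prefix="x", source="generated")
        with pytest.raises(ValueError):
            pg.select_library(real, gen)
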