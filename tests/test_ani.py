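import io

import numpy as np
import pytest

from strainkit.ani import (
    AniParams,
    CategoryAniProfile,
    DistanceMatrix,
    classify_category_regions,
    compute_ani,
    compute_category_ani,
    distance_matrix_from_identity,
    identity_16s,
    nj_tree,
)
from strainkit.io_formats import GeneRecord, GenomeRecord, StrainkitError
from strainkit.synthetic import SimulationConfig, generate_strain_set

from .oracles import hamming_identity_percent


def _random_genome(rng, gid, length):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeRecord(gid, [(f"{gid}_c1", seq)])


def _pair_at_rate(rate, length=30_000, seed=3):
    cfg = SimulationConfig(
        n_strains=2, genome_length=length, genes_per_category={"Q": 8},
        per_category_divergence={"Q": rate}, backbone_divergence=rate,
        divergence_16s=rate, n_hgt_genes=0, crispr_specs=[], seed=seed)
    genomes, _, _, truth = generate_strain_set(cfg)
    return genomes, truth


class TestComputeAni:
    def test_self_ani_is_exactly_100(self):
        rng = np.random.default_rng(0)
        genome = _random_genome(rng, "G", 5100)
        one_way = compute_ani(genome, genome, direction="a->b")
        assert one_way.ani == 100.0
        assert one_way.n_fragments_used == 5
        recip = compute_ani(genome, genome)
        assert recip.ani == 100.0
        assert recip.direction == "reciprocal-mean"

    def test_genome_shorter_than_fragment_rejected(self):
        rng = np.random.default_rng(1)
        genome = _random_genome(rng, "G", 500)
        with pytest.raises(StrainkitError):
            compute_ani(genome, genome)

    def test_recovery_against_coordinate_true_oracle(self):
        # substitution-only divergence keeps homologous windows at equal
        # coordinates, so per-fragment Hamming identity is an exact oracle
        genomes, _ = _pair_at_rate(0.05, length=50_000)
        a, b = genomes
        params = AniParams()
        seq_a, seq_b = a.contigs[0][1], b.contigs[0][1]
        frag = params.fragment_length
        oracle = float(np.mean([
            hamming_identity_percent(seq_a[i:i + frag], seq_b[i:i + frag])
            for i in range(0, len(seq_a) - frag + 1, frag)]))
        result = compute_ani(a, b, params)
        assert result.ani == pytest.approx(oracle, abs=0.5)

    def test_unrelated_random_genomes_hit_the_zero_sentinel(self):
        rng = np.random.default_rng(5)
        a = _random_genome(rng, "A", 20_000)
        b = _random_genome(rng, "B", 20_000)
        result = compute_ani(a, b)
        assert result.n_fragments_used == 0
        assert result.ani == 0.0

    def test_ani_strictly_decreases_with_planted_divergence(self):
        anis = []
        for rate in (0.0, 0.02, 0.05, 0.10, 0.20):
            genomes, _ = _pair_at_rate(rate)
            anis.append(compute_ani(*genomes).ani)
        assert all(x > y for x, y in zip(anis, anis[1:]))
        assert anis[0] == 100.0

    def test_reciprocal_mean_is_mean_of_one_ways(self):
        genomes, _ = _pair_at_rate(0.05)
        res = compute_ani(*genomes)
        ab, ba = res.one_way
        assert res.ani == pytest.approx((ab.ani + ba.ani) / 2)


class TestCategoryAni:
    def _gene(self, gid, genome, cds, cat):
        return GeneRecord(gid, genome, f"{genome}_c1", 0, len(cds), "+",
                          cds=cds, protein="", category=cat)

    def test_identical_category_gene_sets_give_100(self):
        rng = np.random.default_rng(2)
        cds = "".join(rng.choice(list("ACGT"), size=600))
        genes_a = [self._gene("a1", "A", cds, "E")]
        genes_b = [self._gene("b1", "B", cds, "E")]
        profile = compute_category_ani(genes_a, genes_b, {"a1": "E", "b1": "E"})
        assert profile.categories["E"][0] == 100.0

    def test_category_only_in_one_genome_gets_zero_sentinel(self):
        rng = np.random.default_rng(3)
        cds = "".join(rng.choice(list("ACGT"), size=600))
        genes_a = [self._gene("a1", "A", cds, "D")]
        profile = compute_category_ani(genes_a, [], {"a1": "D"})
        assert profile.categories["D"] == (0.0, 0)

    def test_category_absent_from_both_is_omitted(self):
        rng = np.random.default_rng(3)
        cds = "".join(rng.choice(list("ACGT"), size=600))
        genes_a = [self._gene("a1", "A", cds, "E")]
        genes_b = [self._gene("b1", "B", cds, "E")]
        profile = compute_category_ani(genes_a, genes_b, {"a1": "E", "b1": "E"})
        assert set(profile.categories) == {"E"}

    def test_planted_rate_ordering_recovered(self, small_scenario):
        genes = {gid: [] for gid in ("S01", "S02")}
        for g in small_scenario.genes:
            if g.genome_id in genes and g.feature_type == "cds":
                genes[g.genome_id].append(g)
        profile = compute_category_ani(genes["S01"], genes["S02"],
                                       small_scenario.category_map)
        anis = {cat: v[0] for cat, v in profile.categories.items()}
        assert anis["Y"] > anis["M"] > anis["Q"] > anis["D"]


class TestRegionClassification:
    def _profiles(self, cat_values, genome_ani=90.0):
        """cat_values: {category: [per-pair ani]} over pairs AB, AC, BC."""
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        out = []
        for i, (ga, gb) in enumerate(pairs):
            cats = {c: (vals[i], 4 if vals[i] else 0) for c, vals in cat_values.items()}
            out.append(CategoryAniProfile(ga, gb, cats, genome_ani=genome_ani))
        return out

    ID16S = {("A", "B"): 97.0, ("A", "C"): 93.0, ("B", "C"): 93.5}

    def test_three_region_logic(self):
        profiles = self._profiles({
            "U": [95.0, 94.0, 96.0],      # always above the genome line
            "M": [85.0, 84.0, 86.0],      # always below
            "D": [88.0, 0.0, 0.0],        # lost between low-16S pairs
        })
        regions = classify_category_regions(profiles, self.ID16S)
        assert regions.loc["U", "region"] == "upper"
        assert regions.loc["M", "region"] == "middle"
        assert regions.loc["D", "region"] == "divergent"

    def test_zero_at_high_16s_is_not_divergent(self):
        profiles = self._profiles({"X": [0.0, 95.0, 96.0]})
        id16s = {("A", "B"): 97.0, ("A", "C"): 96.0, ("B", "C"): 96.5}
        regions = classify_category_regions(profiles, id16s)
        assert regions.loc["X", "region"] == "middle"   # zero present, so not upper

    def test_requires_three_pairs(self):
        with pytest.raises(StrainkitError):
            classify_category_regions(self._profiles({"U": [95.0, 94.0, 96.0]})[:2],
                                      self.ID16S)


class TestIdentity16s:
    def test_identical_sequences(self):
        assert identity_16s("ACGTACGT", "ACGTACGT") == 100.0

    def test_three_of_four_columns(self):
        assert identity_16s("ACGT", "ACGA") == 75.0

    def test_terminal_gaps_excluded(self):
        assert identity_16s("ACGT", "AC") == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(StrainkitError):
            identity_16s("", "ACGT")

    def test_synthetic_16s_identity_near_expectation(self, default_scenario):
        seqs = {g.genome_id: g.cds for g in default_scenario.genes
                if g.feature_type == "rRNA_16S"}
        observed = identity_16s(seqs["S02"], seqs["S03"])
        expected = default_scenario.truth.expected_identity_16s("S02", "S03")
        assert observed == pytest.approx(expected, abs=1.5)


class TestNeighborJoining:
    def test_three_point_formula(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = nj_tree(dm)
        lengths = {child.name: bl for child, bl in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):3,C:4,D:5)
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        by_name = {}
        internal = []
        for child, bl in tree.root.children:
            if child.name:
                by_name[child.name] = bl
            else:
                internal.append((child, bl))
        assert by_name == {"C": 4.0, "D": 5.0}
        assert len(internal) == 1
        node, bl = internal[0]
        assert bl == pytest.approx(3.0)
        assert {c.name: l for c, l in node.children} == {"A": 1.0, "B": 2.0}

    def test_all_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        labels = list("ABCDE")
        t1 = nj_tree(DistanceMatrix(labels, d)).to_newick()
        t2 = nj_tree(DistanceMatrix(labels, d)).to_newick()
        assert t1 == t2

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(StrainkitError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_matches_reference_neighbor_joining_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        n = 6
        base = rng.uniform(0.2, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(labels, d))
        ours_sk = skbio.TreeNode.read(io.StringIO(ours.to_newick()))
        theirs = skbio_nj(skbio.DistanceMatrix(d, ids=labels))
        rf = ours_sk.compare_rfd(theirs)
        assert rf == 0.0

    def test_distance_matrix_from_identity(self):
        dm = distance_matrix_from_identity(
            ["A", "B"], {("A", "B"): 98.0})
        assert dm.values[0, 1] == pytest.approx(0.02)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(StrainkitError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
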