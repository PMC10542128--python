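"""Clustering, profile-profile merging, representatives, NJ trees."""

import numpy as np
import pytest

from coconut_census import clustering as cl
from coconut_census.profiles import build_profile
from coconut_census.templates import AMINO_ACIDS


def random_seq(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


def mutated(seq, rate, rng):
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(chars)


@pytest.fixture(scope="module")
def families():
    """Two unrelated families of 60-aa proteins, 9 members each."""
    rng = np.random.default_rng(77)
    out = {}
    for name in ("famA", "famB"):
        root = random_seq(rng, 60)
        out[name] = [(f"{name}_{i}", mutated(root, 0.08, rng))
                     for i in range(9)]
    return out


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [(f"s{i}", "MKLVWPTEAG" * 4) for i in range(5)]
        assert len(cl.greedy_cluster(seqs)) == 1

    def test_unrelated_families_split(self, families):
        clusters = cl.greedy_cluster(families["famA"] + families["famB"], 0.5)
        assert len(clusters) == 2
        for cluster in clusters:
            prefixes = {i.split("_")[0] for i in cluster.member_ids()}
            assert len(prefixes) == 1

    def test_threshold_one_gives_singletons(self, families):
        clusters = cl.greedy_cluster(families["famA"], threshold=1.0)
        # members are mutated copies; only exact duplicates would merge
        assert len(clusters) == len({s for _, s in families["famA"]})

    def test_partition_property(self, families):
        seqs = families["famA"] + families["famB"]
        clusters = cl.greedy_cluster(seqs, 0.5)
        seen = [m for c in clusters for m in c.member_ids()]
        assert sorted(seen) == sorted(i for i, _ in seqs)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cl.greedy_cluster([])


class TestAlignCluster:
    def test_single_member_is_itself(self):
        cluster = cl.Cluster("c", [("a", "MKLVW")], "a")
        assert cl.align_cluster(cluster) == [("a", "MKLVW")]

    def test_identical_member_gap_free(self):
        cluster = cl.Cluster("c", [("a", "MKLVWPTE"), ("b", "MKLVWPTE")], "a")
        msa = dict(cl.align_cluster(cluster))
        assert msa["b"] == "MKLVWPTE"

    def test_single_insertion_extends_by_one(self):
        centroid = "MKLVWPTEAGMKLVWPTEAG"
        member = centroid[:10] + "F" + centroid[10:]
        cluster = cl.Cluster("c", [(("a"), member), ("b", centroid)], "a")
        msa = dict(cl.align_cluster(cluster))
        assert len(msa["a"]) == len(member)
        assert msa["b"].count("-") == 1


class TestProfileProfileScore:
    def test_self_score_positive(self, families):
        profile = build_profile([s for _, s in families["famA"]])
        assert cl.profile_profile_score(profile, profile) > 0

    def test_symmetric(self, families):
        pa = build_profile([s for _, s in families["famA"]])
        pb = build_profile([s for _, s in families["famB"]])
        assert cl.profile_profile_score(pa, pb) == \
            pytest.approx(cl.profile_profile_score(pb, pa))

    def test_unrelated_families_ratio_below_merge_threshold(self, families):
        pa = build_profile([s for _, s in families["famA"]])
        pb = build_profile([s for _, s in families["famB"]])
        cross = cl.profile_profile_score(pa, pb)
        ratio = max(cross / cl.profile_profile_score(pa, pa),
                    cross / cl.profile_profile_score(pb, pb))
        assert ratio < 0.1


class TestMergeIterations:
    def make_subfamily_clusters(self, rng, n_sub=3, divergence=0.25):
        """Sub-families of one family, each its own starting cluster."""
        root = random_seq(rng, 60)
        clusters = []
        for k in range(n_sub):
            sub_root = mutated(root, divergence, rng)
            members = [(f"sub{k}_{i}", mutated(sub_root, 0.05, rng))
                       for i in range(6)]
            clusters.append(cl.Cluster(f"c{k}", members, members[0][0]))
        return clusters

    def test_duplicate_profiles_merge_first_iteration(self):
        seqs = [(f"s{i}", "MKLVWPTEAG" * 5) for i in range(6)]
        c1 = cl.Cluster("c1", seqs[:3], seqs[0][0])
        c2 = cl.Cluster("c2", seqs[3:], seqs[3][0])
        merged = cl.merge_iterations([c1, c2], iterations=1)
        assert len(merged) == 1

    def test_converged_clustering_is_fixpoint(self, families):
        clusters = cl.greedy_cluster(families["famA"] + families["famB"], 0.5)
        once = cl.merge_iterations(clusters, iterations=3)
        membership = sorted(tuple(sorted(c.member_ids())) for c in once)
        again = cl.merge_iterations(once, iterations=1)
        membership2 = sorted(tuple(sorted(c.member_ids())) for c in again)
        assert membership == membership2

    def test_subfamilies_merge_unrelated_family_stays(self):
        rng = np.random.default_rng(5)
        subfamilies = self.make_subfamily_clusters(rng)
        other_root = random_seq(rng, 45)
        other = cl.Cluster(
            "other",
            [(f"o{i}", mutated(other_root, 0.05, rng)) for i in range(6)],
            "o0",
        )
        merged = cl.merge_iterations(subfamilies + [other], iterations=3)
        assert len(merged) == 2
        families_out = sorted(
            tuple(sorted({m.split("_")[0].rstrip("0123456789")
                          for m in c.member_ids()}))
            for c in merged
        )
        assert families_out == [("o",), ("sub",)]

    def test_partition_preserved(self, families):
        seqs = families["famA"] + families["famB"]
        clusters = cl.greedy_cluster(seqs, 0.5)
        merged = cl.merge_iterations(clusters, iterations=3)
        members = sorted(m for c in merged for m in c.member_ids())
        assert members == sorted(i for i, _ in seqs)


class TestRepresentatives:
    def test_all_identical_one_representative(self):
        seqs = [(f"s{i}", "MKLVWPTEAG" * 4) for i in range(5)]
        assert len(cl.pick_representatives(seqs)) == 1

    def test_distant_sequences_all_kept(self, families):
        # two unrelated 60-aa families: every cross-pair is far below 0.9
        reps = cl.pick_representatives(
            [families["famA"][0], families["famB"][0]], 0.9
        )
        assert len(reps) == 2

    def test_two_tight_families_two_representatives(self):
        rng = np.random.default_rng(9)
        a_root, b_root = random_seq(rng, 50), random_seq(rng, 50)
        seqs = [(f"a{i}", mutated(a_root, 0.02, rng)) for i in range(5)]
        seqs += [(f"b{i}", mutated(b_root, 0.02, rng)) for i in range(5)]
        assert len(cl.pick_representatives(seqs, 0.9)) == 2


class TestNjTree:
    def test_three_taxa_unique_topology(self, families):
        newick = cl.nj_tree(families["famA"][:3])
        for taxon, _ in families["famA"][:3]:
            assert taxon in newick

    def test_fewer_than_three_errors(self, families):
        with pytest.raises(ValueError):
            cl.nj_tree(families["famA"][:2])

    def test_additive_distances_recover_topology(self):
        """Four-taxon additive matrix: NJ must recover the generating
        split AB|CD."""
        ids = ["A", "B", "C", "D"]
        #      A    B    C    D     (A,B) and (C,D) cherries, internal 0.3
        dm = np.array([
            [0.0, 0.2, 0.7, 0.8],
            [0.2, 0.0, 0.7, 0.8],
            [0.7, 0.7, 0.0, 0.3],
            [0.8, 0.8, 0.3, 0.0],
        ])
        newick = cl.nj_tree_from_distances(dm, ids)
        assert cl.clade_motif_concordance(
            newick, {"A": "x", "B": "x", "C": "y", "D": "y"}
        ) == 1.0

    def test_input_order_invariance(self, families):
        seqs = families["famA"][:5]
        t1 = cl.nj_tree(seqs)
        t2 = cl.nj_tree(list(reversed(seqs)))
        assert t1 == t2


class TestCladeConcordance:
    def test_two_separated_families_full_concordance(self, families):
        reps = families["famA"][:8] + families["famB"][:8]
        newick = cl.nj_tree(reps)
        labels = {i: ("NxD" if i.startswith("famA") else "NxxD")
                  for i, _ in reps}
        assert cl.clade_motif_concordance(newick, labels) == 1.0

    def test_uniform_labels_trivially_concordant(self, families):
        newick = cl.nj_tree(families["famA"][:4])
        labels = {i: "NxD" for i, _ in families["famA"][:4]}
        assert cl.clade_motif_concordance(newick, labels) == 1.0

    def test_random_labels_not_concordant(self, families):
        """Random labels over a 16-leaf two-family tree: brute-force split
        check finds at least one non-monophyletic class."""
        reps = families["famA"][:8] + families["famB"][:8]
        newick = cl.nj_tree(reps)
        rng = np.random.default_rng(123)
        labels = {i: ("x" if rng.random() < 0.5 else "y") for i, _ in reps}
        # guard against a degenerate draw; reseed deterministic above
        assert len(set(labels.values())) == 2
        assert cl.clade_motif_concordance(newick, labels) < 1.0

    def test_unlabeled_leaf_errors(self, families):
        newick = cl.nj_tree(families["famA"][:4])
        with pytest.raises(ValueError, match="unlabeled"):
            cl.clade_motif_concordance(newick, {"famA_0": "x"})


class TestExcision:
    def test_excised_region_spans_walker_to_signature(self):
        from coconut_census.synthetic import design_protein
        d = design_protein("x", ["CSD", "GTPase(NxD)"],
                           np.random.default_rng(3), role="B")
        cut = cl.excise_gtpase(d.seq)
        assert cut is not None
        assert cut.startswith(d.seq[d.walker_a - 1 : d.walker_a + 7])
        assert "NVD" in cut

    def test_no_motif_returns_none(self):
        assert cl.excise_gtpase("MMMMMMMMMM") is None
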