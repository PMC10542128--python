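"""Greedy identity clustering, star alignments, profile-profile merging,
representative selection and neighbor-joining trees.

The cluster/align/merge loop mirrors an MMseqs2 -> MUSCLE -> HHsearch/
HHalign protocol at desk scale: sequences are greedily clustered at a
fraction-identity threshold, each cluster is star-aligned around its
centroid, clusters are compared by global profile-profile alignment, and
pairs whose score-to-self-score ratio exceeds a threshold are merged by
connected components, iterating a fixed number of times.

Identity is exact matches divided by global-alignment length (BLOSUM62
scoring with linear gaps for the alignment itself).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from coconut_census.motifs import scan_gtpase_motifs
from coconut_census.profiles import Profile, build_profile

Seq = tuple[str, str]  # (id, sequence)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -4.0  # linear gap scheme
    aligner.mode = "global"
    return aligner


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """Gapped rows of the best global alignment (first reported optimum)."""
    alignment = _aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_identity(a: str, b: str) -> float:
    """Exact matches / global alignment length."""
    row_a, row_b = global_alignment(a, b)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return matches / len(row_a)


@dataclass
class Cluster:
    cluster_id: str
    members: list[Seq]
    centroid_id: str
    msa: list[Seq] = field(default_factory=list)  # (id, gapped row)
    profile: Profile | None = None
    self_score: float | None = None

    @property
    def centroid_seq(self) -> str:
        return next(s for i, s in self.members if i == self.centroid_id)

    def member_ids(self) -> list[str]:
        return [i for i, _ in self.members]


def greedy_cluster(seqs: list[Seq], threshold: float = 0.5) -> list[Cluster]:
    """Centroid-greedy clustering by descending length.

    Each sequence joins the first existing centroid with pairwise identity
    >= threshold, else founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda s: (-len(s[1]), s[0]))
    clusters: list[Cluster] = []
    for sid, seq in ordered:
        placed = False
        for cluster in clusters:
            if pairwise_identity(seq, cluster.centroid_seq) >= threshold:
                cluster.members.append((sid, seq))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(cluster_id=f"c{len(clusters):04d}",
                        members=[(sid, seq)], centroid_id=sid)
            )
    return clusters


def align_cluster(cluster: Cluster) -> list[Seq]:
    """Star alignment: every member globally aligned to the centroid and
    merged on centroid columns (insertions padded to the longest insert)."""
    centroid = cluster.centroid_seq
    others = [(i, s) for i, s in cluster.members if i != cluster.centroid_id]
    if not others:
        cluster.msa = [(cluster.centroid_id, centroid)]
        return cluster.msa

    # per member: matched[i] = residue aligned to centroid position i (or -),
    # inserts[i] = residues inserted after centroid position i (i=0 -> before)
    L = len(centroid)
    member_rows: list[tuple[str, list[str], dict[int, str]]] = []
    max_insert = [0] * (L + 1)
    for sid, seq in others:
        row_c, row_m = global_alignment(centroid, seq)
        matched = ["-"] * L
        inserts: dict[int, str] = {}
        ci = 0
        for x, y in zip(row_c, row_m):
            if x == "-":
                inserts[ci] = inserts.get(ci, "") + (y if y != "-" else "")
            else:
                matched[ci] = y
                ci += 1
        member_rows.append((sid, matched, inserts))
        for slot, ins in inserts.items():
            max_insert[slot] = max(max_insert[slot], len(ins))

    def build_row(matched: list[str], inserts: dict[int, str]) -> str:
        parts = []
        for i in range(L + 1):
            ins = inserts.get(i, "")
            parts.append(ins + "-" * (max_insert[i] - len(ins)))
            if i < L:
                parts.append(matched[i])
        return "".join(parts)

    msa = [(cluster.centroid_id,
            build_row(list(centroid), {}))]
    for sid, matched, inserts in member_rows:
        msa.append((sid, build_row(matched, inserts)))
    # keep member order stable
    order = {i: n for n, (i, _) in enumerate(cluster.members)}
    msa.sort(key=lambda r: order[r[0]])
    cluster.msa = msa
    return msa


def profile_for_cluster(cluster: Cluster, pseudocount: float = 1.0) -> Profile:
    if not cluster.msa:
        align_cluster(cluster)
    profile = build_profile(
        [row for _, row in cluster.msa], pseudocount, name=cluster.cluster_id
    )
    cluster.profile = profile
    cluster.self_score = profile_profile_score(profile, profile)
    return profile


def profile_profile_score(
    p: Profile, q: Profile, gap_penalty: float = -1.0
) -> float:
    """Global column-to-column alignment score between two profiles.

    Match score for columns c, d is ``log2(sum_a p_c[a] q_d[a] / bg[a])``
    (dot product relative to background, in log space); gaps are linear.
    Symmetric by construction.
    """
    match = np.log2(np.maximum(p.probs @ (q.probs / q.background).T, 1e-12))
    n, m = match.shape
    dp = np.empty((n + 1, m + 1))
    dp[0, :] = np.arange(m + 1) * gap_penalty
    dp[:, 0] = np.arange(n + 1) * gap_penalty
    for i in range(1, n + 1):
        row_prev = dp[i - 1]
        row = dp[i]
        for j in range(1, m + 1):
            row[j] = max(
                row_prev[j - 1] + match[i - 1, j - 1],
                row_prev[j] + gap_penalty,
                row[j - 1] + gap_penalty,
            )
    return float(dp[n, m])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_iterations(
    clusters: list[Cluster], ratio: float = 0.1, iterations: int = 3
) -> list[Cluster]:
    """Iteratively merge similar clusters by profile-profile score ratio.

    Per iteration: all pairwise profile scores; an edge joins two clusters
    when max(score/self_p, score/self_q) > ratio; connected components are
    merged, re-aligned and re-profiled.  A converged clustering is a
    fixpoint: extra iterations change nothing.
    """
    clusters = list(clusters)
    for _ in range(iterations):
        for cluster in clusters:
            if cluster.profile is None:
                profile_for_cluster(cluster)
        n = len(clusters)
        if n <= 1:
            break
        uf = _UnionFind(n)
        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                s = profile_profile_score(clusters[i].profile, clusters[j].profile)
                r = max(s / clusters[i].self_score, s / clusters[j].self_score)
                if r > ratio:
                    uf.union(i, j)
                    merged_any = True
        if not merged_any:
            break
        components: dict[int, list[Cluster]] = {}
        for i, cluster in enumerate(clusters):
            components.setdefault(uf.find(i), []).append(cluster)
        new_clusters: list[Cluster] = []
        for root in sorted(components):
            group = components[root]
            if len(group) == 1:
                new_clusters.append(group[0])
                continue
            members = [m for c in group for m in c.members]
            centroid_id = max(members, key=lambda m: (len(m[1]), m[0]))[0]
            merged = Cluster(
                cluster_id=group[0].cluster_id, members=members,
                centroid_id=centroid_id,
            )
            profile_for_cluster(merged)
            new_clusters.append(merged)
        clusters = new_clusters
    return clusters


def pick_representatives(seqs: list[Seq], threshold: float = 0.9) -> list[Seq]:
    """One centroid per cluster at the given identity threshold."""
    return [
        (c.centroid_id, c.centroid_seq)
        for c in greedy_cluster(seqs, threshold=threshold)
    ]


def nj_tree(representatives: list[Seq]) -> str:
    """Neighbor-joining newick from 1 - identity distances.

    Taxa are sorted by label before the distance matrix is built, so the
    topology is invariant to input order (ties broken by label order).
    """
    if len(representatives) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    reps = sorted(representatives)
    ids = [i for i, _ in reps]
    n = len(reps)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(reps[i][1], reps[j][1])
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids))
    out = io.StringIO()
    tree.write(out)
    return out.getvalue().strip()


def nj_tree_from_distances(dm: np.ndarray, ids: list[str]) -> str:
    """Neighbor-joining directly from a precomputed distance matrix."""
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    dm_sorted = np.asarray(dm)[np.ix_(order, order)]
    tree = nj(DistanceMatrix(dm_sorted, ids_sorted))
    out = io.StringIO()
    tree.write(out)
    return out.getvalue().strip()


def clade_motif_concordance(newick: str, labels: dict[str, str]) -> float:
    """Fraction of motif classes forming monophyletic groups (unrooted).

    A class is monophyletic when its leaf set is one side of some edge
    bipartition (or is trivial: a single leaf or all leaves).
    """
    tree = TreeNode.read(io.StringIO(newick))
    leaves = [t.name for t in tree.tips()]
    unlabeled = [l for l in leaves if l not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled[:5]}")
    all_leaves = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        # every edge (leaf edges included) induces a bipartition
        clade = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        splits.add(clade)
        splits.add(all_leaves - clade)
    classes: dict[str, set[str]] = {}
    for leaf in leaves:
        classes.setdefault(labels[leaf], set()).add(leaf)
    concordant = 0
    for members in classes.values():
        fs = frozenset(members)
        if len(fs) <= 1 or fs == all_leaves or fs in splits:
            concordant += 1
    return concordant / len(classes)


def flag_false_positive_clusters(
    clusters: list[Cluster],
    positive_profiles: list[Profile],
    negative_profiles: list[Profile],
) -> set[str]:
    """Clusters scoring better against negative controls than positives.

    Flagged (never deleted): the counterpart of a manual screen for
    unrelated AAA+ family clusters caught by permissive searches.
    """
    flagged: set[str] = set()
    for cluster in clusters:
        if cluster.profile is None:
            profile_for_cluster(cluster)
        best_pos = max(
            (profile_profile_score(cluster.profile, p) for p in positive_profiles),
            default=float("-inf"),
        )
        best_neg = max(
            (profile_profile_score(cluster.profile, p) for p in negative_profiles),
            default=float("-inf"),
        )
        if best_neg > best_pos:
            flagged.add(cluster.cluster_id)
    return flagged


def excise_gtpase(seq: str, margin: int = 30) -> str | None:
    """Cut the GTPase domain: Walker A through signature motif + margin."""
    call = scan_gtpase_motifs(seq)
    if call.walker_a_pos is None or call.d_pos is None:
        return None
    start = max(0, call.walker_a_pos - 1)
    end = min(len(seq), call.d_pos + margin)
    return seq[start:end]
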