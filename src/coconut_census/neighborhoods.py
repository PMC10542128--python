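"""Genomic-neighborhood extraction and three-tier candidate filtering.

A candidate locus ("island") is an anchor hit plus up to 10 genes on each
side.  Islands pass through three mutually exclusive tiers, applied in
order:

* primary — the island carries a direct McrB GTPase (COG1401-equivalent)
  hit, or at least one McrB-alias and one McrC-alias hit;
* rescue-single — exactly one alias side is present, but a gene adjacent
  to the alias hit (intergenic gap <= 90 nt, same strand) is large enough
  to supply the missing role (> 200 aa for McrB, > 150 aa for McrC);
* rescue-none — no alias hits at all, but the profile-search anchor has
  an operonic neighbor of sufficient size for the missing role;
* otherwise the island is rejected.

Overlapping genes (negative gap) count as within 90 nt: overlap is the
tightest operonic association.  Size gates are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

from coconut_census.genome_io import GeneFeature, GenomeRecord, intergenic_gap
from coconut_census.profiles import SearchHit
from coconut_census.templates import DISCOVERY_ROLE
from coconut_census.vocab import DEFAULT_VOCAB, AliasVocabulary

GAP_MAX_NT = 90
SIZE_MIN_B = 200  # strict: candidate must exceed this
SIZE_MIN_C = 150

TIERS = ("primary", "rescue-single", "rescue-none", "rejected")
ACCEPTED_TIERS = ("primary", "rescue-single", "rescue-none")


@dataclass
class Island:
    island_id: str
    anchor_gene_id: str
    genes: list[GeneFeature]
    truncated_left: bool = False
    truncated_right: bool = False
    tier: str | None = None
    anchor_role: str | None = None  # role of the discovery profile (B or C)

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    @property
    def anchor(self) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == self.anchor_gene_id:
                return g
        raise KeyError(self.anchor_gene_id)


def extract_island(
    genome: GenomeRecord, anchor_gene_id: str, k: int = 10,
    island_id: str | None = None,
) -> Island:
    """Up to ``k`` genes each side of the anchor, in genomic order."""
    idx = genome.index_of(anchor_gene_id)
    lo = max(0, idx - k)
    hi = min(len(genome.genes), idx + k + 1)
    return Island(
        island_id=island_id or f"isl_{anchor_gene_id}",
        anchor_gene_id=anchor_gene_id,
        genes=list(genome.genes[lo:hi]),
        truncated_left=(idx - k < 0),
        truncated_right=(idx + k + 1 > len(genome.genes)),
    )


def _alias_sides(island: Island, vocab: AliasVocabulary) -> tuple[bool, bool, bool]:
    """(has direct GTPase, has any B alias, has any C alias)."""
    has_gtpase = has_b = has_c = False
    for gene in island.genes:
        for hit in gene.annotations:
            if vocab.is_gtpase(hit.domain_label):
                has_gtpase = True
            if vocab.is_mcrb_alias(hit.domain_label):
                has_b = True
            if vocab.is_mcrc_alias(hit.domain_label):
                has_c = True
    return has_gtpase, has_b, has_c


def primary_filter(island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB) -> bool:
    """Direct GTPase hit, or both an McrB alias and an McrC alias present."""
    has_gtpase, has_b, has_c = _alias_sides(island, vocab)
    return has_gtpase or (has_b and has_c)


def _adjacent_candidates(island: Island, gene: GeneFeature):
    """Neighbors of ``gene`` consecutive in the island's genomic order."""
    idx = next(i for i, g in enumerate(island.genes) if g.gene_id == gene.gene_id)
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(island.genes):
            yield island.genes[j]


def _operonic_partner(
    island: Island, gene: GeneFeature, size_min: int,
    gap_max: int = GAP_MAX_NT,
) -> GeneFeature | None:
    """An adjacent, same-strand gene with gap <= gap_max and length > size_min."""
    for neighbor in _adjacent_candidates(island, gene):
        if neighbor.strand != gene.strand:
            continue
        if intergenic_gap(gene, neighbor) > gap_max:
            continue
        if neighbor.protein_length > size_min:
            return neighbor
    return None


def rescue_single_alias(
    island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB,
    gap_max: int = GAP_MAX_NT, size_b: int = SIZE_MIN_B, size_c: int = SIZE_MIN_C,
) -> bool:
    """Exactly one alias side present; an operonic neighbor supplies the rest.

    When the McrB side is missing the candidate must exceed ``size_b`` aa;
    when the McrC side is missing, ``size_c`` aa.
    """
    has_gtpase, has_b, has_c = _alias_sides(island, vocab)
    if has_gtpase or (has_b and has_c) or not (has_b or has_c):
        return False
    missing_size = size_b if has_c else size_c
    for gene in island.genes:
        labels = {h.domain_label for h in gene.annotations}
        is_alias_gene = any(
            (vocab.is_mcrb_alias(l) if has_b else vocab.is_mcrc_alias(l))
            for l in labels
        )
        if not is_alias_gene:
            continue
        if _operonic_partner(island, gene, missing_size, gap_max) is not None:
            return True
    return False


def rescue_no_alias(
    island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB,
    gap_max: int = GAP_MAX_NT, size_b: int = SIZE_MIN_B, size_c: int = SIZE_MIN_C,
) -> bool:
    """No alias hits anywhere, but the anchor has an operonic partner.

    The partner's size gate depends on the role the anchor's discovery
    profile testifies to: a B-side anchor needs a partner large enough to
    be the McrC (> size_c), and vice versa.  When the anchor role is
    unknown the stricter McrB gate applies.
    """
    has_gtpase, has_b, has_c = _alias_sides(island, vocab)
    if has_gtpase or has_b or has_c:
        return False
    missing_size = size_c if island.anchor_role == "B" else size_b
    return _operonic_partner(island, island.anchor, missing_size, gap_max) is not None


def classify_island(
    island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB, **kw
) -> str:
    if primary_filter(island, vocab):
        tier = "primary"
    elif rescue_single_alias(island, vocab, **kw):
        tier = "rescue-single"
    elif rescue_no_alias(island, vocab, **kw):
        tier = "rescue-none"
    else:
        tier = "rejected"
    island.tier = tier
    return tier


def classify_islands(
    genomes: list[GenomeRecord],
    discovery_hits: list[SearchHit],
    vocab: AliasVocabulary = DEFAULT_VOCAB,
    k: int = 10,
    gap_max: int = GAP_MAX_NT,
    size_b: int = SIZE_MIN_B,
    size_c: int = SIZE_MIN_C,
) -> list[Island]:
    """One classified island per discovery anchor, deduplicated by span.

    Anchors are the distinct genes carrying discovery hits; when several
    anchors yield identical gene spans only the first (by genomic order)
    island is kept.
    """
    by_contig = {g.contig_id: g for g in genomes}
    anchor_role: dict[str, str] = {}
    for hit in discovery_hits:
        role = DISCOVERY_ROLE.get(hit.profile_name)
        if hit.gene_id not in anchor_role and role is not None:
            anchor_role[hit.gene_id] = role
    # genomic enumeration order for determinism
    anchors: list[tuple[str, GeneFeature]] = []
    for genome in genomes:
        for gene in genome.genes:
            if gene.gene_id in anchor_role:
                anchors.append((genome.contig_id, gene))
    islands: list[Island] = []
    seen_spans: set[tuple[str, ...]] = set()
    for i, (contig_id, gene) in enumerate(anchors):
        island = extract_island(
            by_contig[contig_id], gene.gene_id, k=k, island_id=f"isl{i:05d}"
        )
        island.anchor_role = anchor_role[gene.gene_id]
        span = island.gene_ids()
        if span in seen_spans:
            continue
        seen_spans.add(span)
        classify_island(island, vocab, gap_max=gap_max, size_b=size_b, size_c=size_c)
        islands.append(island)
    return islands
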