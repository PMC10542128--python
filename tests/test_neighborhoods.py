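"""Island extraction and the three-tier neighborhood filter."""

import pytest

from coconut_census import neighborhoods as nb
from coconut_census import profiles as pf
from coconut_census.genome_io import DomainHit, GeneFeature, GenomeRecord
from coconut_census.synthetic import PlantSpec, generate_cohort
from coconut_census.templates import ANNOTATION_LABELS, DISCOVERY_LABELS


def build_genome(specs, contig="c"):
    """specs: list of (gene_id, gap_to_previous, length_aa, strand, labels)."""
    genes = []
    cursor = 0
    for gene_id, gap, length_aa, strand, labels in specs:
        start = cursor + gap + 1
        end = start + 3 * (length_aa + 1) - 1
        gene = GeneFeature(gene_id=gene_id, contig_id=contig, start=start,
                           end=end, strand=strand, protein_length=length_aa)
        for label in labels:
            gene.annotations.append(
                DomainHit(domain_label=label, start_aa=1,
                          end_aa=min(30, length_aa), evalue=1e-9)
            )
        genes.append(gene)
        cursor = end
    return GenomeRecord(contig, cursor + 100, genes)


def island_of(genome, anchor, **kw):
    return nb.extract_island(genome, anchor, **kw)


class TestExtractIsland:
    @pytest.fixture()
    def genome(self):
        return build_genome(
            [(f"g{i}", 200, 100, "+", []) for i in range(25)]
        )

    def test_full_island_has_21_genes(self, genome):
        island = island_of(genome, "g12")
        assert len(island.genes) == 21
        assert not island.truncated_left and not island.truncated_right

    def test_first_gene_truncated_left(self, genome):
        island = island_of(genome, "g0")
        assert len(island.genes) == 11
        assert island.truncated_left and not island.truncated_right

    def test_k_zero_is_anchor_only(self, genome):
        island = island_of(genome, "g5", k=0)
        assert [g.gene_id for g in island.genes] == ["g5"]

    def test_unknown_anchor_errors(self, genome):
        with pytest.raises(KeyError):
            island_of(genome, "nope")


class TestPrimaryFilter:
    def test_direct_gtpase_hit_suffices(self):
        genome = build_genome([("a", 100, 300, "+", ["GTPase"])])
        assert nb.primary_filter(island_of(genome, "a"))

    def test_both_alias_sides(self):
        genome = build_genome([
            ("a", 100, 300, "+", ["EVE"]),
            ("b", 100, 300, "+", ["DUF2357"]),
        ])
        assert nb.primary_filter(island_of(genome, "a"))

    def test_single_alias_fails_primary(self):
        genome = build_genome([("a", 100, 300, "+", ["EVE"])])
        assert not nb.primary_filter(island_of(genome, "a"))


class TestRescueSingleAlias:
    def rescue(self, gap, partner_len, partner_strand="+", alias="DUF2357"):
        genome = build_genome([
            ("alias", 150, 200, "+", [alias]),
            ("cand", gap, partner_len, partner_strand, []),
        ])
        return nb.rescue_single_alias(island_of(genome, "alias"))

    def test_gap_90_passes_gap_91_fails(self):
        assert self.rescue(gap=90, partner_len=250)
        assert not self.rescue(gap=91, partner_len=250)

    def test_mcrb_size_gate_strict(self):
        assert self.rescue(gap=50, partner_len=201)
        assert not self.rescue(gap=50, partner_len=200)

    def test_mcrc_size_gate_strict(self):
        # alias is on the McrB side -> candidate supplies McrC (> 150 aa)
        genome_ok = build_genome([
            ("alias", 150, 300, "+", ["EVE"]),
            ("cand", 50, 151, "+", []),
        ])
        genome_small = build_genome([
            ("alias", 150, 300, "+", ["EVE"]),
            ("cand", 50, 150, "+", []),
        ])
        assert nb.rescue_single_alias(island_of(genome_ok, "alias"))
        assert not nb.rescue_single_alias(island_of(genome_small, "alias"))

    def test_opposite_strand_fails(self):
        assert not self.rescue(gap=50, partner_len=250, partner_strand="-")

    def test_overlap_counts_as_within(self):
        assert self.rescue(gap=-10, partner_len=250)

    def test_not_applicable_when_primary_holds(self):
        genome = build_genome([
            ("a", 100, 300, "+", ["GTPase"]),
            ("b", 50, 250, "+", []),
        ])
        assert not nb.rescue_single_alias(island_of(genome, "a"))


class TestRescueNoAlias:
    def island(self, partner_len, partner_strand="+", gap=60, role="B"):
        genome = build_genome([
            ("anchor", 150, 300, "+", []),
            ("cand", gap, partner_len, partner_strand, []),
        ])
        isl = island_of(genome, "anchor")
        isl.anchor_role = role
        return isl

    def test_b_anchor_needs_mcrc_sized_partner(self):
        assert nb.rescue_no_alias(self.island(partner_len=160))
        assert not nb.rescue_no_alias(self.island(partner_len=150))

    def test_opposite_strand_partner_fails(self):
        assert not nb.rescue_no_alias(self.island(partner_len=300,
                                                  partner_strand="-"))

    def test_anchor_alone_fails(self):
        genome = build_genome([("anchor", 150, 300, "+", [])])
        isl = island_of(genome, "anchor")
        isl.anchor_role = "B"
        assert not nb.rescue_no_alias(isl)

    def test_alias_presence_disqualifies(self):
        genome = build_genome([
            ("anchor", 150, 300, "+", ["EVE"]),
            ("cand", 60, 300, "+", []),
        ])
        assert not nb.rescue_no_alias(island_of(genome, "anchor"))


@pytest.fixture(scope="module")
def classified():
    mix = [
        PlantSpec(subtype="mcrbc-classic"),
        PlantSpec(subtype="pseudo-I-B", filter_design="rescue-single",
                  rescue_gap=89),
        PlantSpec(subtype="pseudo-I-B", filter_design="rescue-none"),
        PlantSpec(subtype="decoy"),
    ]
    genomes, truths = generate_cohort(2, mix=mix, seed=31)
    discovery = pf.builtin_profiles(DISCOVERY_LABELS)
    annotation = pf.builtin_profiles(ANNOTATION_LABELS)
    pf.calibrate_all(discovery + annotation, seed=0)
    pf.search_proteome(annotation, genomes, evalue_max=0.001, attach=True)
    hits = pf.search_proteome(discovery, genomes, evalue_max=10.0,
                              attach=False)
    islands = nb.classify_islands(genomes, hits)
    return genomes, truths, islands


class TestClassifyIslands:
    def tier_for(self, truths, islands, predicate):
        tiers = []
        for truth in truths:
            if not predicate(truth):
                continue
            member_set = set(truth.member_gene_ids)
            matching = [i for i in islands if member_set & set(i.gene_ids())]
            tiers.append((truth.system_id,
                          sorted({i.tier for i in matching})))
        return tiers

    def test_planted_classic_is_primary(self, classified):
        _, truths, islands = classified
        for sid, tiers in self.tier_for(
            truths, islands, lambda t: t.subtype == "mcrbc-classic"
        ):
            assert "primary" in tiers, sid

    def test_planted_rescue_single_tier(self, classified):
        _, truths, islands = classified
        rows = self.tier_for(truths, islands,
                             lambda t: t.filter_design == "rescue-single")
        assert rows
        for sid, tiers in rows:
            assert "rescue-single" in tiers, sid

    def test_planted_rescue_none_tier(self, classified):
        _, truths, islands = classified
        rows = self.tier_for(truths, islands,
                             lambda t: t.filter_design == "rescue-none")
        assert rows
        for sid, tiers in rows:
            assert "rescue-none" in tiers, sid

    def test_decoys_never_accepted(self, classified):
        _, truths, islands = classified
        decoy_genes = {g for t in truths if t.subtype == "decoy"
                       for g in t.member_gene_ids}
        for island in islands:
            if island.tier in nb.ACCEPTED_TIERS:
                assert island.anchor_gene_id not in decoy_genes


class TestTierMonotonicity:
    def test_adding_annotations_never_demotes(self):
        """Tier order primary > rescue-single > rescue-none > rejected is
        monotone under added domain evidence."""
        rank = {t: i for i, t in enumerate(
            ["rejected", "rescue-none", "rescue-single", "primary"])}
        genome = build_genome([
            ("anchor", 150, 300, "+", []),
            ("cand", 60, 250, "+", []),
        ])
        isl = island_of(genome, "anchor")
        isl.anchor_role = "B"
        before = nb.classify_island(isl)
        # add a single-side alias -> rescue-single; then a C alias -> primary
        genome.genes[0].annotations.append(
            DomainHit("EVE", 1, 30, 1e-9))
        mid = nb.classify_island(island_of(genome, "anchor"))
        genome.genes[1].annotations.append(
            DomainHit("DUF2357", 1, 30, 1e-9))
        after = nb.classify_island(island_of(genome, "anchor"))
        assert rank[before] <= rank[mid] <= rank[after]
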