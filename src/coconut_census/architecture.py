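"""Domain-architecture assembly and CoCoNuT subtype classification.

Paired McrB/McrC systems are classified by a fixed rule cascade over the
domain architectures and motif calls of the island's genes, applied
most-specific-first (III-B, III-C, III-A, II, I-A, I-B, pseudo-I-B, I-C)
so that Type II rules — a strict subset of Type III-A's features — never
shadow III-A.  The CoCoNuT prerequisite is an NxD GTPase signature on
the CnuB/McrB gene: NxxD/NxxxD systems are valid McrBC but non-CoCoNuT.

Also here: the TerY-P (VWA + PP2C + STK-zinc-ribbon) accessory triad
detector and the CARF/RtcR-anchored superoperon walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from coconut_census.coils import CoilSegment, predict_segments
from coconut_census.genome_io import GeneFeature, GenomeRecord, intergenic_gap
from coconut_census.motifs import (
    HepnCall,
    MotifCall,
    detect_helical_insert,
    find_hepn_motifs,
    scan_gtpase_motifs,
)
from coconut_census.neighborhoods import Island
from coconut_census.pairing import PairedSystem
from coconut_census.templates import reference_gtpase_sequence

CHAIN_GAP_MAX = 200  # nt; superoperon close-spacing threshold
INSERT_MIN = 30  # aa; Type I-A helical insert


@dataclass
class DomainArchitecture:
    gene_id: str
    ordered_domains: list[str]
    spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SubtypeCall:
    system_id: str
    subtype: str
    evidence: list[str] = field(default_factory=list)
    confidence: str = "full"


@dataclass
class SuperoperonRecord:
    anchor_gene_id: str
    chain_gene_ids: list[str]
    span_nt: int
    systems_in_order: list[str]
    rm_first: bool
    coconut_last: bool


def gene_architecture(
    gene: GeneFeature,
    coil_segments: list[CoilSegment] | None = None,
) -> DomainArchitecture:
    """Ordered domain string from annotations plus coiled-coil segments.

    Domains are ordered by start position; coiled-coil calls enter the
    architecture as ``CC`` pseudo-domains.
    """
    entries: list[tuple[int, int, str]] = [
        (h.start_aa, h.end_aa, h.domain_label) for h in gene.annotations
    ]
    if coil_segments is None and gene.protein_seq:
        coil_segments = predict_segments(gene.protein_seq, gene.gene_id)
    for seg in coil_segments or []:
        entries.append((seg.start_aa, seg.end_aa, "CC"))
    entries.sort()
    return DomainArchitecture(
        gene_id=gene.gene_id,
        ordered_domains=[label for _, _, label in entries],
        spans=[(s, e) for s, e, _ in entries],
    )


def has_helical_insert(
    seq: str, insert_min: int = INSERT_MIN, window: int = 200
) -> bool:
    """Test a GTPase-bearing protein for the Type I-A helical insert.

    The protein is aligned against the insert-free canonical GTPase
    reference; residues between Walker B and the signature motif that do
    not align to the reference count as inserted.
    """
    from coconut_census.clustering import global_alignment

    ref = reference_gtpase_sequence()
    call = scan_gtpase_motifs(seq, window=window)
    if call.walker_a_pos is None or call.n_pos is None:
        return False
    # cut to the GTPase region to keep the alignment local to the domain
    start = max(0, call.walker_a_pos - 15)
    end = min(len(seq), call.d_pos + 20)
    region = seq[start:end]
    row_ref, row_mem = global_alignment(ref, region)
    msa = [("ref", row_ref), ("member", row_mem)]
    try:
        return detect_helical_insert(msa, "member", insert_min=insert_min,
                                     window=window)
    except ValueError:
        return False


@dataclass
class SystemContext:
    """Everything the subtype cascade looks at for one paired system."""

    system: PairedSystem
    island: Island
    architectures: dict[str, DomainArchitecture]
    motif_calls: dict[str, MotifCall]
    hepn_calls: dict[str, list[HepnCall]]
    insert_flags: dict[str, bool]

    def arch(self, gene_id: str) -> list[str]:
        a = self.architectures.get(gene_id)
        return a.ordered_domains if a else []

    def genes_with(self, *labels: str) -> list[str]:
        """Island genes whose architecture contains all the given labels."""
        out = []
        for gene in self.island.genes:
            domains = self.arch(gene.gene_id)
            if all(l in domains for l in labels):
                out.append(gene.gene_id)
        return out


def build_context(
    system: PairedSystem,
    island: Island,
    coil_segments: dict[str, list[CoilSegment]] | None = None,
) -> SystemContext:
    """Assemble architectures and motif calls for the cascade."""
    architectures: dict[str, DomainArchitecture] = {}
    motif_calls: dict[str, MotifCall] = {}
    hepn_calls: dict[str, list[HepnCall]] = {}
    insert_flags: dict[str, bool] = {}
    for gene in island.genes:
        segs = (coil_segments or {}).get(gene.gene_id)
        architectures[gene.gene_id] = gene_architecture(gene, segs)
        seq = gene.protein_seq or ""
        if "GTPase" in architectures[gene.gene_id].ordered_domains:
            motif_calls[gene.gene_id] = scan_gtpase_motifs(seq, gene.gene_id,
                                                           window=200)
            insert_flags[gene.gene_id] = has_helical_insert(seq)
        hepn_spans = [
            (h.start_aa, min(h.end_aa + 10, len(seq)))
            for h in gene.annotations if h.domain_label == "HEPN"
        ]
        calls: list[HepnCall] = []
        for span in hepn_spans:
            calls.extend(find_hepn_motifs(seq, span, gene.gene_id))
        if calls:
            hepn_calls[gene.gene_id] = calls
    return SystemContext(
        system=system, island=island, architectures=architectures,
        motif_calls=motif_calls, hepn_calls=hepn_calls,
        insert_flags=insert_flags,
    )


def _hepn_motif_set(ctx: SystemContext, gene_id: str) -> list[str]:
    return [c.motif for c in ctx.hepn_calls.get(gene_id, [])]


def type_coconut(ctx: SystemContext) -> SubtypeCall:
    """Apply the subtype rule cascade to one paired system."""
    system = ctx.system
    b_id, c_id = system.mcrb_gene_id, system.mcrc_gene_id
    call = SubtypeCall(system_id=system.system_id, subtype="non-coconut")
    if not ctx.architectures:
        raise ValueError("architectures missing for island genes")

    motif = ctx.motif_calls.get(b_id)
    if motif is None or motif.motif_class != "NxD":
        call.evidence = [
            f"signature:{motif.motif_class if motif else 'absent'}"
        ]
        return call

    b_arch = ctx.arch(b_id)
    c_arch = ctx.arch(c_id)

    # --- Type III-B: Sul7s-wHTH + helicase + fused Vsr, separate Hsp70 gene
    helicase_vsr = ctx.genes_with("SF1-helicase", "Sul7s-wHTH", "Vsr")
    cnu_d = [g for g in ctx.genes_with("Hsp70-NBD/SBD")
             if "HEAT" not in ctx.arch(g) and g != c_id]
    if helicase_vsr and cnu_d:
        call.subtype = "III-B"
        call.evidence = ["III-B:helicase-Vsr-fusion", "III-B:separate-CnuD"]
        return call

    # --- Type III-C: effector with wHTH + two PLD nucleases, separate CnuD
    pld_effectors = [
        g for g in ctx.genes_with("wHTH", "PLD")
        if ctx.arch(g).count("PLD") >= 2
    ]
    if pld_effectors and cnu_d:
        call.subtype = "III-C"
        call.evidence = ["III-C:wHTH-2xPLD-effector", "III-C:separate-CnuD"]
        return call

    # --- Type III-A: CnuE with two HEPN (RxxxxH + RxH), CnuC with Hsp70+HEAT
    cnu_e_2hepn = [
        g for g in ctx.genes_with("wHTH", "HEPN")
        if _hepn_motif_set(ctx, g).count("RxxxxH") >= 1
        and "RxH" in _hepn_motif_set(ctx, g)
    ]
    c_hsp70_heat = "Hsp70-NBD/SBD" in c_arch and "HEAT" in c_arch
    if cnu_e_2hepn and c_hsp70_heat:
        call.subtype = "III-A"
        call.evidence = ["III-A:two-HEPN-RxxxxH+RxH", "III-A:CnuC-Hsp70-HEAT"]
        return call

    # --- Type II: CnuE with one HEPN (RxxxxH), CnuH with SPB+RTL+OB-stalk
    cnu_e_1hepn = [
        g for g in ctx.genes_with("wHTH", "HEPN")
        if _hepn_motif_set(ctx, g) == ["RxxxxH"]
    ]
    cnu_h = ctx.genes_with("SPB", "RTL", "OB-stalk", "SF1-helicase")
    if cnu_e_1hepn and cnu_h:
        call.subtype = "II"
        call.evidence = ["II:CnuE-single-RxxxxH", "II:CnuH-SPB-RTL-OB"]
        return call

    # --- Type I-A: helical insert in the CnuB GTPase
    if ctx.insert_flags.get(b_id):
        call.subtype = "I-A"
        call.evidence = ["I-A:helical-insert"]
        return call

    # --- Type I-B: separate CnuA (PYD + CC + REC)
    cnu_a = ctx.genes_with("PYD", "CC", "REC")
    has_yth = "YTH" in b_arch
    if cnu_a:
        call.subtype = "I-B"
        call.evidence = ["I-B:separate-CnuA-PYD-CC-REC"]
        if not has_yth:
            call.confidence = "partial"
            call.evidence.append("optional-YTH-missing")
        return call

    # --- pseudo-I-B: I-B-like CnuB/CnuC, coiled-coil not fused, no CnuA
    if "CSD" in b_arch and "CC" not in b_arch:
        call.subtype = "pseudo-I-B"
        call.evidence = ["pseudo-I-B:no-CnuA", "pseudo-I-B:no-fused-CC"]
        if not has_yth:
            call.confidence = "partial"
            call.evidence.append("optional-YTH-missing:candidate-I-C")
        return call

    # --- Type I-C: CnuB with CSD (+YTH) + fused CC, two-gene system
    if "CSD" in b_arch and "CC" in b_arch:
        call.subtype = "I-C"
        call.evidence = ["I-C:CnuB-CSD-CC-fusion"]
        if not has_yth:
            call.confidence = "partial"
            call.evidence.append("optional-YTH-missing")
        return call

    call.subtype = "coconut-unclassified"
    call.evidence = ["NxD-GTPase-without-subtype-architecture"]
    call.confidence = "partial"
    return call


def detect_tery_p(island: Island) -> bool:
    """TerY-P triad: VWA, PP2C and STK genes on one strand in the island."""
    for strand in ("+", "-"):
        labels_present = set()
        for gene in island.genes:
            if gene.strand != strand:
                continue
            for hit in gene.annotations:
                labels_present.add(hit.domain_label)
        if {"VWA", "PP2C", "STK"} <= labels_present:
            return True
    return False


SYSTEM_LABELS = {
    "HsdR": "TypeI-RM", "HsdM": "TypeI-RM", "HsdS": "TypeI-RM",
    "Mod": "TypeIII-RM", "Res": "TypeIII-RM",
    "ShdA": "ShdA", "Druantia": "Druantia",
}
CARF_LABELS = {"CARF", "RtcR-ATPase"}


def _gene_system_label(gene: GeneFeature) -> str | None:
    for hit in gene.annotations:
        if hit.domain_label in CARF_LABELS:
            return "CARF"
        if hit.domain_label in SYSTEM_LABELS:
            return SYSTEM_LABELS[hit.domain_label]
    return None


def detect_superoperon(
    genome: GenomeRecord,
    system_gene_ids: list[str],
    chain_gap_max: int = CHAIN_GAP_MAX,
) -> SuperoperonRecord | None:
    """Walk upstream from a CoCoNuT along its strand to a CARF/RtcR anchor.

    Collects consecutive same-strand genes with intergenic gaps at most
    ``chain_gap_max``; any strand flip or larger gap breaks the chain.  If
    a CARF/RtcR gene is reached, returns the chain with the ancillary
    systems between the anchor and the CoCoNuT in 5'-to-3' order,
    ``rm_first`` (Type I RM directly after the CARF gene) and
    ``coconut_last`` (nothing, or only Druantia, downstream in-chain).
    """
    members = [g for g in genome.genes if g.gene_id in system_gene_ids]
    if not members:
        return None
    strand = members[0].strand
    idx = {g.gene_id: i for i, g in enumerate(genome.genes)}
    first = min(idx[g.gene_id] for g in members)
    last = max(idx[g.gene_id] for g in members)
    upstream_step = -1 if strand == "+" else 1
    edge = first if strand == "+" else last

    chain: list[GeneFeature] = []
    i = edge
    while True:
        j = i + upstream_step
        if j < 0 or j >= len(genome.genes):
            break
        prev, nxt = genome.genes[i], genome.genes[j]
        if nxt.strand != strand:
            break
        if intergenic_gap(prev, nxt) > chain_gap_max:
            break
        chain.append(nxt)
        i = j
        if _gene_system_label(nxt) == "CARF":
            break
    if not chain or _gene_system_label(chain[-1]) != "CARF":
        return None
    anchor = chain[-1]

    # chain genes in transcription (5'->3') order: anchor ... coconut
    between = chain[:-1][::-1]
    systems: list[str] = []
    for gene in between:
        label = _gene_system_label(gene)
        if label and (not systems or systems[-1] != label):
            systems.append(label)
    systems_full = systems + ["CoCoNuT"]

    # downstream of the CoCoNuT: does anything but Druantia follow in-chain?
    coconut_last = True
    i = last if strand == "+" else first
    while True:
        j = i + (1 if strand == "+" else -1)
        if j < 0 or j >= len(genome.genes):
            break
        prev, nxt = genome.genes[i], genome.genes[j]
        if nxt.strand != strand or intergenic_gap(prev, nxt) > chain_gap_max:
            break
        label = _gene_system_label(nxt)
        if label and label not in ("Druantia",):
            coconut_last = False
        i = j

    chain_ids = [anchor.gene_id] + [g.gene_id for g in between] + [
        g.gene_id for g in sorted(members, key=lambda g: idx[g.gene_id])
    ]
    coords = [genome.genes[idx[g]].start for g in chain_ids] + [
        genome.genes[idx[g]].end for g in chain_ids
    ]
    return SuperoperonRecord(
        anchor_gene_id=anchor.gene_id,
        chain_gene_ids=chain_ids,
        span_nt=max(coords) - min(coords) + 1,
        systems_in_order=systems_full,
        rm_first=bool(systems) and systems[0] == "TypeI-RM",
        coconut_last=coconut_last,
    )
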