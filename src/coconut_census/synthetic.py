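"""Synthetic prokaryotic genomes with planted McrBC/CoCoNuT systems.

Generates annotated contigs of ordered, stranded protein-coding genes:
planted systems of every subtype with the canonical operon layouts, gap
distributions (including overlapping reading frames as negative gaps),
decoy genes carrying McrB-alias domains without a partner, and matched
truth tables.  Proteins are assembled from the fixed domain templates in
:mod:`coconut_census.templates`, so the built-in profile scanner, motif
scanner and coiled-coil predictor recover every planted feature exactly
at mutation rate 0.

Planted cassettes are separated by at least 11 background genes so that a
10-gene-per-side neighborhood around any anchor contains exactly one
cassette; background intergenic gaps are kept above the 90-nt operonic
adjacency threshold so no background gene can satisfy a rescue filter by
chance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from coconut_census.genome_io import GeneFeature, GenomeRecord, write_genome, write_report
from coconut_census.templates import (
    AMINO_ACIDS,
    gtpase_variant,
    CPXC_UNITS,
    HEPN_MOTIFS,
    HEPTAD,
    PDDXK_ACTIVE,
    PDDXK_INACTIVE,
    SIGNATURES,
    TEMPLATES,
    _rand,
)
from coconut_census.vocab import PLANT_SUBTYPES

# Canonical operon layouts: (gene name, architecture, role).  Roles drive
# protein length targets (McrB-role 201-600 aa, McrC-role 151-500 aa so the
# strict size gates pass by construction).
SUBTYPE_LAYOUTS: dict[str, list[tuple[str, list[str], str]]] = {
    "mcrbc-classic": [
        ("mcrB", ["DUF3578", "GTPase(NxxD)"], "B"),
        ("mcrC", ["DUF2357", "PD-DxK"], "C"),
    ],
    "I-A": [
        ("cnuB", ["CSD", "CC", "GTPase(NxD,insert)"], "B"),
        ("cnuC", ["IG", "DUF2357", "CSD", "PD-DxK", "ZnR(3)"], "C"),
    ],
    "I-B": [
        ("cnuA", ["PYD", "CC", "REC"], "other"),
        ("cnuB", ["CSD", "YTH", "GTPase(NxD)"], "B"),
        ("cnuC", ["IG", "DUF2357", "PD-DxK"], "C"),
    ],
    "pseudo-I-B": [
        ("cnuB", ["CSD", "YTH", "GTPase(NxD)"], "B"),
        ("cnuC", ["IG", "DUF2357", "PD-DxK"], "C"),
    ],
    "I-C": [
        ("cnuB", ["CSD", "YTH", "CC", "GTPase(NxD)"], "B"),
        ("cnuC", ["IG", "DUF2357", "PD-DxK", "ZnR(3)"], "C"),
    ],
    "II": [
        ("cnuH", ["SPB", "RTL", "OB-stalk", "SF1-helicase"], "other"),
        ("cnuE", ["wHTH", "CC", "HEPN(RxxxxH)"], "other"),
        ("cnuB", ["CC", "GTPase(NxD)"], "B"),
        ("cnuC", ["IG", "DUF2357", "iPD-DxK", "ZnR(2)"], "C"),
        ("terY", ["VWA"], "other"),
        ("terP", ["PP2C"], "other"),
        ("terK", ["STK", "ZnR(1)"], "other"),
    ],
    "III-A": [
        ("cnuH", ["SPB", "RTL", "OB-stalk", "SF1-helicase"], "other"),
        ("cnuE", ["wHTH", "CC", "HEPN(RxxxxH)", "HEPN(RxH)"], "other"),
        ("cnuB", ["CC", "GTPase(NxD)", "HTH"], "B"),
        ("cnuC", ["DUF2357", "Hsp70-NBD/SBD", "HEAT"], "C"),
        ("terY", ["VWA"], "other"),
        ("terP", ["PP2C"], "other"),
        ("terK", ["STK", "ZnR(1)"], "other"),
    ],
    "III-B": [
        ("cnuH", ["Sul7s-wHTH", "SF1-helicase", "Vsr"], "other"),
        ("cnuA", ["CC"], "other"),
        ("cnuD", ["Hsp70-NBD/SBD"], "other"),
        ("cnuB", ["CC", "GTPase(NxD)"], "B"),
        ("cnuC", ["DUF2357", "iPD-DxK"], "C"),
    ],
    "III-C": [
        ("cnuH", ["SF1-helicase"], "other"),
        ("cnuE", ["wHTH", "PLD", "PLD"], "other"),
        ("cnuD", ["Hsp70-NBD/SBD"], "other"),
        ("cnuB", ["CC", "GTPase(NxD)"], "B"),
        ("cnuC", ["DUF2357", "iPD-DxK"], "C"),
    ],
}

TERY_GENES = {"terY", "terP", "terK"}
DECOY_DOMAINS = ("EVE", "MoxR", "Smc", "DUF4357", "Mrr_N", "AAA_5")

ROLE_LENGTH = {"B": (260, 400), "C": (210, 340), "other": (250, 420)}
DECOY_LENGTH = (180, 320)
BACKGROUND_LENGTH = (90, 180)
# Background gaps stay above the 90-nt adjacency threshold.
BACKGROUND_GAP = (120, 400)
CASSETTE_SPACING = 11  # background genes between planted cassettes


@dataclass(frozen=True)
class GapModel:
    """Intergenic gap distribution within planted operons.

    With probability ``overlap_prob`` the gap is a negative draw from
    ``overlap_range`` (overlapping reading frames); otherwise a uniform
    draw from ``gap_range``.  All values stay within the 90-nt operonic
    adjacency used by the rescue filters.
    """

    overlap_prob: float = 0.3
    overlap_range: tuple[int, int] = (-20, -1)
    gap_range: tuple[int, int] = (0, 60)

    def sample(self, rng: np.random.Generator) -> int:
        if rng.random() < self.overlap_prob:
            return int(rng.integers(self.overlap_range[0], self.overlap_range[1] + 1))
        return int(rng.integers(self.gap_range[0], self.gap_range[1] + 1))


@dataclass(frozen=True)
class PlantSpec:
    """Specification for one planted system (or decoy)."""

    subtype: str
    gap_model: GapModel = GapModel()
    orientation_policy: str = "same-strand"  # same-strand | reversed-order | intervening:k
    mutation_rate: float = 0.0
    seed: int = 0
    strand: str = "+"
    # primary: passes the alias filter outright; rescue-single / rescue-none
    # plant the corresponding degenerate neighborhoods instead.
    filter_design: str = "primary"
    rescue_gap: int = 60
    protect_motifs: bool = True

    def __post_init__(self) -> None:
        if self.subtype not in PLANT_SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class GeneDesign:
    """Planted truth for a single protein."""

    name: str
    role: str
    seq: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)
    walker_a: int | None = None
    walker_b: int | None = None
    motif_class: str | None = None
    n_pos: int | None = None
    d_pos: int | None = None
    following: str | None = None
    hepn: list[tuple[str, int, int, int]] = field(default_factory=list)  # motif,pos,span
    cpxc_count: int = 0
    helical_insert: bool = False
    coiled_coil: list[tuple[int, int]] = field(default_factory=list)
    protected: set[int] = field(default_factory=set)  # 1-based positions


@dataclass
class TruthRecord:
    """Ground truth for one planted system."""

    system_id: str
    subtype: str
    member_gene_ids: list[str]
    designed_to_pass_filter: bool
    planted_motifs: list[tuple[str, str]]
    strand: str = "+"
    layout: str = "canonical"
    filter_design: str = "primary"
    b_gene_id: str | None = None
    c_gene_id: str | None = None
    tery_p_gene_ids: list[str] = field(default_factory=list)
    gene_designs: dict[str, GeneDesign] = field(default_factory=dict)


_ELEMENT_RE = re.compile(r"^(?P<label>[^()]+?)(?:\((?P<args>[^()]*)\))?$")


def _parse_element(element: str) -> tuple[str, list[str]]:
    m = _ELEMENT_RE.match(element)
    if m is None:
        raise ValueError(f"cannot parse architecture element {element!r}")
    args = [a.strip() for a in m.group("args").split(",")] if m.group("args") else []
    return m.group("label"), args


def _element_sequence(
    label: str, args: list[str], rng: np.random.Generator, design: GeneDesign, offset: int
) -> str:
    """Build one domain element; record truth at 1-based ``offset``."""

    def protect(start: int, length: int) -> None:
        design.protected.update(range(start, start + length))

    if label == "CC":
        seg = HEPTAD * 6
        design.coiled_coil.append((offset, offset + len(seg) - 1))
        design.domains.append(("CC", offset, offset + len(seg) - 1))
        protect(offset, len(seg))
        return seg

    if label in ("GTPase", "GTPase_cryptic"):
        variant = args[0] if args else "NxD"
        insert = "insert" in args
        core, pos_a, pos_b, post_spacer, tail = gtpase_variant(label, variant)
        parts = [core]
        pos = len(core)
        if insert:
            parts.append(_rand(rng, 40))
            pos += 40
            design.helical_insert = True
        parts.append(post_spacer)
        pos += len(post_spacer)
        sig = SIGNATURES[variant]
        parts.append(sig)
        design.walker_a = offset + pos_a - 1
        design.walker_b = offset + pos_b - 1
        design.motif_class = variant
        design.n_pos = offset + pos
        design.d_pos = offset + pos + len(sig) - 2
        design.following = sig[-1]
        parts.append(tail)
        seq = "".join(parts)
        design.domains.append((label, offset, offset + len(core) - 1))
        protect(design.walker_a, len("GPSGSGKS"))
        protect(design.walker_b, len("ILVIDE"))
        protect(design.n_pos, len(sig))
        return seq

    if label == "HEPN":
        motif = args[0] if args else "RxxxxH"
        lead = TEMPLATES["HEPN"].core[: -len(HEPN_MOTIFS["RxxxxH"])]
        seg = lead + HEPN_MOTIFS[motif]
        mpos = offset + len(lead)
        design.hepn.append((motif, mpos, offset, offset + len(seg) - 1))
        design.domains.append(("HEPN", offset, offset + len(seg) - 1))
        protect(mpos, len(HEPN_MOTIFS[motif]))
        return seg

    if label in ("PD-DxK", "iPD-DxK"):
        tmpl = TEMPLATES["PD-DxK"]
        core = tmpl.core
        if label == "iPD-DxK":
            core = core.replace(PDDXK_ACTIVE, PDDXK_INACTIVE)
        design.domains.append((label, offset, offset + len(core) - 1))
        cat_start = core.index(PDDXK_ACTIVE if label == "PD-DxK" else PDDXK_INACTIVE)
        protect(offset + cat_start, len(PDDXK_ACTIVE))
        return core

    if label == "ZnR":
        n = int(args[0]) if args else 1
        core = TEMPLATES["ZnR"].core
        deco = "GS" + "GSSG".join(CPXC_UNITS[:n])
        seg = core + deco
        design.domains.append(("ZnR", offset, offset + len(core) - 1))
        design.cpxc_count += n
        protect(offset + len(core), len(deco))
        return seg

    tmpl = TEMPLATES.get(label)
    if tmpl is None:
        raise ValueError(f"unknown domain label {label!r}")
    design.domains.append((label, offset, offset + len(tmpl.core) - 1))
    return tmpl.core


def design_protein(
    name: str,
    architecture: list[str],
    rng: np.random.Generator,
    role: str = "other",
    target_len: int | None = None,
) -> GeneDesign:
    """Assemble a protein from domain elements with linkers and padding."""
    design = GeneDesign(name=name, role=role, seq="")
    parts: list[str] = [_rand(rng, 4)]
    pos = 5  # next free 1-based position
    for i, element in enumerate(architecture):
        if i > 0:
            linker = _rand(rng, int(rng.integers(8, 15)))
            parts.append(linker)
            pos += len(linker)
        label, args = _parse_element(element)
        seg = _element_sequence(label, args, rng, design, pos)
        parts.append(seg)
        pos += len(seg)
    seq = "".join(parts)
    if target_len is None:
        lo, hi = ROLE_LENGTH.get(role, (250, 420))
        target_len = int(rng.integers(lo, hi + 1))
    if len(seq) < target_len:
        seq += _rand(rng, target_len - len(seq))
    design.seq = seq
    return design


def make_protein(architecture: list[str], seed: int) -> str:
    """Deterministic protein for an ordered domain architecture."""
    rng = np.random.default_rng(seed)
    return design_protein("protein", architecture, rng).seq


def mutate(design: GeneDesign, rate: float, rng: np.random.Generator,
           protect_motifs: bool = True) -> GeneDesign:
    """Apply i.i.d. substitutions; planted motif positions optionally kept."""
    if rate <= 0:
        return design
    chars = list(design.seq)
    for i in range(len(chars)):
        if protect_motifs and (i + 1) in design.protected:
            continue
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
    out = replace(design)
    out.seq = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# Genome assembly


class _ContigBuilder:
    """Appends genes left to right on a growing contig."""

    def __init__(self, contig_id: str) -> None:
        self.contig_id = contig_id
        self.genes: list[GeneFeature] = []
        self._cursor = 0  # end coordinate of last gene

    def add_gene(self, gene_id: str, seq: str, strand: str, gap: int) -> GeneFeature:
        nt_len = 3 * (len(seq) + 1)
        start = self._cursor + gap + 1
        if start < 1:
            start = 1
        end = start + nt_len - 1
        gene = GeneFeature(
            gene_id=gene_id, contig_id=self.contig_id, start=start, end=end,
            strand=strand, protein_length=len(seq), protein_seq=seq,
        )
        self.genes.append(gene)
        self._cursor = end
        return gene

    def record(self) -> GenomeRecord:
        length = self._cursor + 200
        return GenomeRecord(self.contig_id, length, list(self.genes))


def _background_gene(builder: _ContigBuilder, idx: int, rng: np.random.Generator) -> None:
    length = int(rng.integers(*BACKGROUND_LENGTH))
    strand = "+" if rng.random() < 0.5 else "-"
    gap = int(rng.integers(*BACKGROUND_GAP))
    builder.add_gene(f"{builder.contig_id}_bg{idx:04d}", _rand(rng, length), strand, gap)


def _rescue_layout(spec: PlantSpec) -> list[tuple[str, list[str], str]]:
    if spec.filter_design == "rescue-single":
        return [("partner", [], "B"), ("cnuC", ["DUF2357"], "C")]
    if spec.filter_design == "rescue-none":
        return [("cnuB", ["GTPase_cryptic(NxD)"], "B"), ("partner", [], "C")]
    raise ValueError(spec.filter_design)


def plant_system(
    builder: _ContigBuilder, spec: PlantSpec, system_id: str,
    rng: np.random.Generator,
) -> TruthRecord:
    """Append one cassette to the contig and return its truth record."""
    if spec.subtype == "decoy":
        domain = DECOY_DOMAINS[rng.integers(0, len(DECOY_DOMAINS))]
        length = int(rng.integers(*DECOY_LENGTH))
        design = design_protein("decoy", [domain], rng, target_len=length)
        design = mutate(design, spec.mutation_rate, rng, spec.protect_motifs)
        gene_id = f"{system_id}_decoy"
        gap = int(rng.integers(*BACKGROUND_GAP))
        builder.add_gene(gene_id, design.seq, spec.strand, gap)
        return TruthRecord(
            system_id=system_id, subtype="decoy", member_gene_ids=[gene_id],
            designed_to_pass_filter=False, planted_motifs=[],
            strand=spec.strand, filter_design="decoy",
            gene_designs={gene_id: design},
        )

    if spec.filter_design != "primary":
        layout = _rescue_layout(spec)
    else:
        layout = SUBTYPE_LAYOUTS[spec.subtype]

    # canonical transcription order -> optionally reversed / intervening
    order = list(layout)
    policy = spec.orientation_policy
    if policy == "reversed-order":
        b_idx = next(i for i, (_, _, r) in enumerate(order) if r == "B")
        c_idx = next(i for i, (_, _, r) in enumerate(order) if r == "C")
        order[b_idx], order[c_idx] = order[c_idx], order[b_idx]
    n_intervening = 0
    if policy.startswith("intervening:"):
        n_intervening = int(policy.split(":", 1)[1])

    designs: list[GeneDesign] = []
    for gene_name, architecture, role in order:
        d = design_protein(gene_name, architecture, rng, role=role)
        d = mutate(d, spec.mutation_rate, rng, spec.protect_motifs)
        designs.append(d)

    # insert plain intervening genes between B and C where requested
    if n_intervening:
        out: list[GeneDesign] = []
        roles = [d.role for d in designs]
        first_bc = min(roles.index("B"), roles.index("C"))
        for i, d in enumerate(designs):
            out.append(d)
            if i == first_bc:
                for k in range(n_intervening):
                    out.append(design_protein(f"mid{k}", [], rng, target_len=120))
        designs = out

    # genomic order: on the minus strand the operon runs right-to-left
    genomic = designs if spec.strand == "+" else list(reversed(designs))
    truth = TruthRecord(
        system_id=system_id, subtype=spec.subtype, member_gene_ids=[],
        designed_to_pass_filter=True, planted_motifs=[], strand=spec.strand,
        layout=policy, filter_design=spec.filter_design,
    )
    for i, design in enumerate(genomic):
        gene_id = f"{system_id}_{design.name}"
        if spec.filter_design == "rescue-single" and i == 1:
            gap = spec.rescue_gap
        elif spec.filter_design == "rescue-none" and i == 1:
            gap = spec.rescue_gap
        elif i == 0:
            gap = int(rng.integers(*BACKGROUND_GAP))
        else:
            gap = spec.gap_model.sample(rng)
        builder.add_gene(gene_id, design.seq, spec.strand, gap)
        truth.member_gene_ids.append(gene_id)
        truth.gene_designs[gene_id] = design
        if design.name in TERY_GENES:
            truth.tery_p_gene_ids.append(gene_id)
        if design.role == "B":
            truth.b_gene_id = gene_id
        elif design.role == "C":
            truth.c_gene_id = gene_id
        if design.motif_class:
            truth.planted_motifs.append((gene_id, design.motif_class))
        for motif, _pos, _s, _e in design.hepn:
            truth.planted_motifs.append((gene_id, motif))
        if design.cpxc_count:
            truth.planted_motifs.append((gene_id, f"CPxC:{design.cpxc_count}"))
    return truth


def default_mix() -> list[PlantSpec]:
    """One system of each subtype plus five decoys — the census condition."""
    specs = [PlantSpec(subtype=s) for s in (
        "mcrbc-classic", "I-A", "I-B", "pseudo-I-B", "I-C", "II",
        "III-A", "III-B", "III-C",
    )]
    specs += [PlantSpec(subtype="decoy")] * 5
    return specs


def generate_cohort(
    n_genomes: int,
    mix: list[PlantSpec] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[GenomeRecord], list[TruthRecord]]:
    """Generate ``n_genomes`` contigs, each planted with the given mix.

    Deterministic under ``seed``; optionally writes GFF3 + protein FASTA +
    truth TSV into ``out_dir``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if mix is None:
        mix = default_mix()
    master = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    truths: list[TruthRecord] = []
    bg_counter = 0
    for gi in range(n_genomes):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        contig = f"ctg{gi:03d}"
        builder = _ContigBuilder(contig)
        order = list(rng.permutation(len(mix)))
        sys_counter = 0
        for mi in order:
            spec = mix[mi]
            strand = "+" if rng.random() < 0.7 else "-"
            spec = replace(spec, strand=strand)
            for _ in range(CASSETTE_SPACING):
                _background_gene(builder, bg_counter, rng)
                bg_counter += 1
            system_id = f"{contig}_sys{sys_counter:02d}"
            truths.append(plant_system(builder, spec, system_id, rng))
            sys_counter += 1
        for _ in range(CASSETTE_SPACING):
            _background_gene(builder, bg_counter, rng)
            bg_counter += 1
        genomes.append(builder.record())

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genomes, out / "genomes.gff3", out / "proteins.faa")
        write_truth_table(truths, out / "truth.tsv")
    return genomes, truths


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "system_id": t.system_id,
            "subtype": t.subtype,
            "member_gene_ids": ",".join(t.member_gene_ids),
            "designed_to_pass_filter": t.designed_to_pass_filter,
            "planted_motifs": ";".join(f"{g}:{m}" for g, m in t.planted_motifs),
            "strand": t.strand,
            "layout": t.layout,
            "filter_design": t.filter_design,
            "b_gene_id": t.b_gene_id,
            "c_gene_id": t.c_gene_id,
        }
        for t in truths
    ]
    write_report(rows, path)


# ---------------------------------------------------------------------------
# CARF-anchored superoperon planting (Type II CoCoNuT tail)

SUPEROPERON_PLAN: list[tuple[str, list[str], int, str]] = [
    # (gene name, architecture, protein length, system label)
    ("carf", ["CARF", "RtcR-ATPase"], 420, "CARF"),
    ("hsdR", ["HsdR"], 1100, "TypeI-RM"),
    ("hsdM", ["HsdM"], 780, "TypeI-RM"),
    ("hsdS", ["HsdS"], 440, "TypeI-RM"),
    ("mod", ["Mod"], 650, "TypeIII-RM"),
    ("res", ["Res"], 950, "TypeIII-RM"),
    ("shdA", ["ShdA"], 2400, "ShdA"),
    ("dru1", ["Druantia"], 700, "Druantia"),
    ("dru2", ["Druantia"], 700, "Druantia"),
    ("dru3", ["Druantia"], 700, "Druantia"),
    ("dru4", ["Druantia"], 700, "Druantia"),
    ("dru5", ["Druantia"], 700, "Druantia"),
    ("cnuH", ["SPB", "RTL", "OB-stalk", "SF1-helicase"], 900, "CoCoNuT"),
    ("cnuE", ["wHTH", "CC", "HEPN(RxxxxH)"], 480, "CoCoNuT"),
    ("cnuB", ["CC", "GTPase(NxD)"], 320, "CoCoNuT"),
    ("cnuC", ["IG", "DUF2357", "iPD-DxK", "ZnR(2)"], 380, "CoCoNuT"),
]


def plant_superoperon(
    seed: int = 0,
    contig_id: str = "ctg_super",
    interrupt: bool = False,
) -> tuple[GenomeRecord, TruthRecord]:
    """One contig with a same-strand CARF -> Type I RM -> ... -> CoCoNuT chain.

    The chain spans roughly 38 kb.  With ``interrupt=True`` an
    opposite-strand gene is placed between the restriction systems and the
    CoCoNuT, which must break the chain walk.
    """
    rng = np.random.default_rng(seed)
    builder = _ContigBuilder(contig_id)
    for i in range(3):
        _background_gene(builder, i, rng)
    truth = TruthRecord(
        system_id=f"{contig_id}_sys00", subtype="II", member_gene_ids=[],
        designed_to_pass_filter=True, planted_motifs=[], strand="+",
        filter_design="primary",
    )
    for name, architecture, length, _system in SUPEROPERON_PLAN:
        if interrupt and name == "cnuH":
            builder.add_gene(f"{contig_id}_interrupt", _rand(rng, 150), "-", 80)
        gene_id = f"{contig_id}_{name}"
        design = design_protein(name, architecture, rng, target_len=length)
        gap = int(rng.integers(40, 150))
        builder.add_gene(gene_id, design.seq, "+", gap)
        truth.member_gene_ids.append(gene_id)
        truth.gene_designs[gene_id] = design
        if name == "cnuB":
            truth.b_gene_id = gene_id
        if name == "cnuC":
            truth.c_gene_id = gene_id
        if design.motif_class:
            truth.planted_motifs.append((gene_id, design.motif_class))
    for i in range(3, 6):
        _background_gene(builder, i, rng)
    return builder.record(), truth
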