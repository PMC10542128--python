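"""End-to-end census orchestration with deterministic seeding.

``run_census`` executes: profile calibration -> discovery search ->
island extraction and tier filtering -> McrB-McrC pairing -> motif and
coiled-coil scanning -> subtype typing -> TerY-P and superoperon
detection -> candidate clustering, merging and tree building -> report
bundle (TSVs, newick, JSON manifest).  Every stage writes a
self-describing table keyed by island/system ids so the whole funnel
can be audited, and two runs with the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from coconut_census import architecture as arch_mod
from coconut_census import clustering, motifs, neighborhoods, pairing, profiles
from coconut_census.genome_io import GenomeRecord, read_genome, write_report
from coconut_census.neighborhoods import ACCEPTED_TIERS, Island
from coconut_census.templates import ANNOTATION_LABELS, DISCOVERY_LABELS
from coconut_census.vocab import DEFAULT_VOCAB


@dataclass
class CensusConfig:
    """All pipeline thresholds; defaults are the published values."""

    out_dir: str | None = None
    gff_path: str | None = None
    fasta_path: str | None = None
    external_hits_path: str | None = None
    evalue_discovery: float = 10.0
    evalue_domains: float = 0.001
    neighborhood_k: int = 10
    gap_max: int = 90
    size_b: int = 200
    size_c: int = 150
    cluster_threshold: float = 0.5
    merge_ratio: float = 0.1
    iterations: int = 3
    final_iterations: int = 10
    reps_threshold: float = 0.9
    insert_min: int = 30
    chain_gap_max: int = 200
    search_rounds: int = 2
    calibration_shuffles: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


PAPER_DEFAULTS = CensusConfig()


def validate_config(config: CensusConfig) -> list[str]:
    """Errors on invalid values; warns about deviations from the defaults."""
    for name in (
        "evalue_discovery", "evalue_domains", "gap_max", "size_b", "size_c",
        "cluster_threshold", "merge_ratio", "reps_threshold", "insert_min",
        "chain_gap_max", "neighborhood_k",
    ):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    if config.iterations < 1 or config.final_iterations < 1:
        raise ValueError("iteration counts must be >= 1")
    if config.search_rounds < 1:
        raise ValueError("search_rounds must be >= 1")
    warnings = []
    for name in (
        "evalue_discovery", "evalue_domains", "gap_max", "size_b", "size_c",
        "cluster_threshold", "merge_ratio", "iterations", "final_iterations",
        "reps_threshold", "insert_min", "chain_gap_max",
    ):
        default = getattr(PAPER_DEFAULTS, name)
        value = getattr(config, name)
        if value != default:
            warnings.append(f"{name}={value} deviates from published value {default}")
    return warnings


@dataclass
class CensusResult:
    genomes: list[GenomeRecord]
    islands: list[Island]
    systems: list[pairing.PairedSystem]
    subtype_calls: dict[str, arch_mod.SubtypeCall]
    orphans: list[dict]
    superoperons: list[arch_mod.SuperoperonRecord]
    tery_p: dict[str, bool]
    tree_newick: str | None
    concordance: float | None
    manifest: dict
    motif_calls: dict[str, motifs.MotifCall] = field(default_factory=dict)

    def accepted_islands(self) -> list[Island]:
        return [i for i in self.islands if i.tier in ACCEPTED_TIERS]


_PATH_FIELDS = ("out_dir", "gff_path", "fasta_path", "external_hits_path")


def _science_params(config: CensusConfig) -> dict:
    """Config without filesystem paths: the part that defines the analysis."""
    return {k: v for k, v in config.to_dict().items()
            if k not in _PATH_FIELDS}


def _config_hash(config: CensusConfig) -> str:
    payload = json.dumps(_science_params(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_census(
    config: CensusConfig,
    genomes: list[GenomeRecord] | None = None,
) -> CensusResult:
    """Run the full census over provided (or loaded) genomes."""
    validate_config(config)
    if genomes is None:
        if not config.gff_path or not config.fasta_path:
            raise ValueError("provide genomes or gff_path+fasta_path")
        genomes = read_genome(config.gff_path, config.fasta_path)
    # fresh annotation state so reruns are reproducible
    for genome in genomes:
        for gene in genome.genes:
            gene.annotations = []

    manifest: dict = {
        "config": _science_params(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = manifest["stages"]

    # --- profiles & calibration
    discovery = profiles.builtin_profiles(DISCOVERY_LABELS)
    annotation = profiles.builtin_profiles(ANNOTATION_LABELS)
    profiles.calibrate_all(discovery + annotation,
                           n_shuffles=config.calibration_shuffles,
                           seed=config.seed)
    stage["profiles"] = {"discovery": len(discovery), "annotation": len(annotation)}

    # --- domain annotation (E = 0.001) and discovery search (E <= 10)
    ann_hits = profiles.search_proteome(
        annotation, genomes, evalue_max=config.evalue_domains, attach=True
    )
    if config.external_hits_path:
        profiles.import_external_hits(config.external_hits_path, genomes)
    disc_hits = profiles.search_proteome(
        discovery, genomes, evalue_max=config.evalue_discovery, attach=False
    )
    stage["search"] = {"annotation_hits": len(ann_hits),
                       "discovery_hits": len(disc_hits)}

    # --- islands & tiers
    islands = neighborhoods.classify_islands(
        genomes, disc_hits, DEFAULT_VOCAB, k=config.neighborhood_k,
        gap_max=config.gap_max, size_b=config.size_b, size_c=config.size_c,
    )
    accepted = [i for i in islands if i.tier in ACCEPTED_TIERS]
    stage["islands"] = {
        "total": len(islands),
        **{t: sum(1 for i in islands if i.tier == t)
           for t in neighborhoods.TIERS},
    }

    # --- pairing
    systems: list[pairing.PairedSystem] = []
    island_of: dict[str, Island] = {}
    for island in accepted:
        for system in pairing.pair_systems(island):
            systems.append(system)
            island_of[system.system_id] = island
    # resolve duplicates: the same operon is reached from several anchors,
    # and overlapping islands can propose conflicting pairings for one
    # gene.  Keep each gene in at most one system, preferring the tightest
    # (smallest |gap|) pairing — operonic proximity is the pairing signal.
    systems.sort(key=lambda s: (abs(s.gap_nt),
                                s.layout != "canonical", s.system_id))
    used_genes: set[str] = set()
    unique_systems = []
    for system in systems:
        if system.mcrb_gene_id in used_genes or system.mcrc_gene_id in used_genes:
            continue
        used_genes.update((system.mcrb_gene_id, system.mcrc_gene_id))
        unique_systems.append(system)
    unique_systems.sort(key=lambda s: s.system_id)
    systems = unique_systems
    orphans = pairing.report_orphans(accepted)
    stage["pairing"] = {"systems": len(systems), "orphans": len(orphans)}

    # --- typing + accessory modules
    subtype_calls: dict[str, arch_mod.SubtypeCall] = {}
    motif_calls: dict[str, motifs.MotifCall] = {}
    tery_p: dict[str, bool] = {}
    superoperons: list[arch_mod.SuperoperonRecord] = []
    by_contig = {g.contig_id: g for g in genomes}
    for system in systems:
        island = island_of[system.system_id]
        # typing context: the neighborhood centered on the system's own
        # McrB gene, so edge-truncated discovery islands cannot leak a
        # neighboring locus's genes into the rule cascade
        genome = by_contig[island.anchor.contig_id]
        context_island = neighborhoods.extract_island(
            genome, system.mcrb_gene_id, k=config.neighborhood_k,
            island_id=island.island_id,
        )
        ctx = arch_mod.build_context(system, context_island)
        subtype_calls[system.system_id] = arch_mod.type_coconut(ctx)
        if system.mcrb_gene_id in ctx.motif_calls:
            motif_calls[system.mcrb_gene_id] = ctx.motif_calls[system.mcrb_gene_id]
        tery_p[system.system_id] = arch_mod.detect_tery_p(context_island)
        if subtype_calls[system.system_id].subtype not in (
            "non-coconut", "coconut-unclassified",
        ):
            record = arch_mod.detect_superoperon(
                genome, [system.mcrb_gene_id, system.mcrc_gene_id],
                chain_gap_max=config.chain_gap_max,
            )
            if record is not None:
                superoperons.append(record)
    subtype_counts: dict[str, int] = {}
    for c in subtype_calls.values():
        subtype_counts[c.subtype] = subtype_counts.get(c.subtype, 0) + 1
    stage["typing"] = {
        "subtypes": dict(sorted(subtype_counts.items())),
        "superoperons": len(superoperons),
    }

    # --- clustering of McrB-role candidates + tree
    b_seqs: list[tuple[str, str]] = []
    seen_genes: set[str] = set()
    for system in systems:
        island = island_of[system.system_id]
        gene = island.anchor if system.mcrb_gene_id == island.anchor_gene_id \
            else next(g for g in island.genes if g.gene_id == system.mcrb_gene_id)
        if gene.gene_id in seen_genes or not gene.protein_seq:
            continue
        seen_genes.add(gene.gene_id)
        excised = clustering.excise_gtpase(gene.protein_seq)
        b_seqs.append((gene.gene_id, excised or gene.protein_seq))

    tree_newick = None
    concordance = None
    n_clusters = 0
    if b_seqs:
        clusters = clustering.greedy_cluster(b_seqs, config.cluster_threshold)
        clusters = clustering.merge_iterations(
            clusters, ratio=config.merge_ratio, iterations=config.iterations
        )
        n_clusters = len(clusters)
        reps = clustering.pick_representatives(b_seqs, config.reps_threshold)
        if len(reps) >= 3:
            tree_newick = clustering.nj_tree(reps)
            labels = {}
            for rid, seq in reps:
                call = motifs.scan_gtpase_motifs(seq)
                labels[rid] = call.motif_class
            try:
                concordance = clustering.clade_motif_concordance(tree_newick, labels)
            except ValueError:
                concordance = None
    stage["clustering"] = {"input": len(b_seqs), "clusters": n_clusters}

    result = CensusResult(
        genomes=genomes, islands=islands, systems=systems,
        subtype_calls=subtype_calls, orphans=orphans,
        superoperons=superoperons, tery_p=tery_p,
        tree_newick=tree_newick, concordance=concordance,
        manifest=manifest, motif_calls=motif_calls,
    )
    if config.out_dir:
        write_bundle(result, Path(config.out_dir))
    return result


def write_bundle(result: CensusResult, out_dir: Path) -> None:
    """Write the deterministic report bundle."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(
        [
            {
                "island_id": i.island_id, "tier": i.tier,
                "anchor": i.anchor_gene_id,
                "n_genes": len(i.genes),
                "truncated_left": i.truncated_left,
                "truncated_right": i.truncated_right,
                "genes": ",".join(i.gene_ids()),
            }
            for i in result.islands
        ],
        out_dir / "islands.tsv",
    )
    write_report(
        [
            {
                "system_id": s.system_id, "island_id": s.island_id,
                "mcrb_gene_id": s.mcrb_gene_id, "mcrc_gene_id": s.mcrc_gene_id,
                "layout": s.layout, "gap_nt": s.gap_nt,
                "low_confidence": s.low_confidence,
                "subtype": result.subtype_calls[s.system_id].subtype,
                "confidence": result.subtype_calls[s.system_id].confidence,
                "evidence": ";".join(result.subtype_calls[s.system_id].evidence),
                "tery_p": result.tery_p.get(s.system_id, False),
            }
            for s in result.systems
        ],
        out_dir / "systems.tsv",
    )
    write_report(result.orphans, out_dir / "orphans.tsv",
                 columns=["island_id", "gene_id", "role", "best_domain",
                          "best_evalue"])
    write_report(
        [
            {
                "anchor_gene_id": r.anchor_gene_id,
                "span_nt": r.span_nt,
                "systems_in_order": ";".join(r.systems_in_order),
                "rm_first": r.rm_first,
                "coconut_last": r.coconut_last,
                "chain": ",".join(r.chain_gene_ids),
            }
            for r in result.superoperons
        ],
        out_dir / "superoperons.tsv",
    )
    if result.tree_newick:
        (out_dir / "mcrb_tree.nwk").write_text(result.tree_newick + "\n")
    manifest = dict(result.manifest)
    manifest["concordance"] = result.concordance
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
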