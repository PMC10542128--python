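"""McrB-McrC pairing within accepted islands.

Homolog roles are assigned from domain evidence; B- and C-role genes are
paired one-to-one by minimum total genomic distance (scipy's assignment
solver), tolerating reversed operon order, intervening genes and
multi-copy islands.  Unpaired role-carrying genes are reported as orphans
for manual triage, never auto-promoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from coconut_census.genome_io import GeneFeature, intergenic_gap
from coconut_census.neighborhoods import Island
from coconut_census.vocab import DEFAULT_VOCAB, AliasVocabulary

# Tiny tie-break penalties: prefer canonical (B upstream of C) layouts,
# then earlier gene order, among assignments of equal genomic distance.
_REVERSED_PENALTY = 1e-4
_ORDER_PENALTY = 1e-7
LOW_CONFIDENCE_INTERVENING = 3


@dataclass
class PairedSystem:
    system_id: str
    mcrb_gene_id: str
    mcrc_gene_id: str
    layout: str  # canonical | reversed | intervening:k
    gap_nt: int
    island_id: str
    low_confidence: bool = False


def pair_candidates(
    island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB
) -> tuple[list[GeneFeature], list[GeneFeature]]:
    """Split island genes into McrB-role and McrC-role candidate lists.

    A gene with evidence for both roles takes the role of its strongest
    (lowest-evalue) hit.
    """
    b_roles: list[GeneFeature] = []
    c_roles: list[GeneFeature] = []
    for gene in island.genes:
        b_hit = gene.best_hit(
            {l for l in {h.domain_label for h in gene.annotations}
             if vocab.is_mcrb_alias(l)}
        )
        c_hit = gene.best_hit(
            {l for l in {h.domain_label for h in gene.annotations}
             if vocab.is_mcrc_alias(l)}
        )
        if b_hit is None and c_hit is None:
            continue
        if c_hit is None or (b_hit is not None and b_hit.evalue <= c_hit.evalue):
            b_roles.append(gene)
        else:
            c_roles.append(gene)
    return b_roles, c_roles


def _layout(island: Island, b: GeneFeature, c: GeneFeature) -> tuple[str, int]:
    """Layout label and intervening-gene count for a candidate pair."""
    order = {g.gene_id: i for i, g in enumerate(island.genes)}
    bi, ci = order[b.gene_id], order[c.gene_id]
    k = abs(bi - ci) - 1
    if k > 0:
        return f"intervening:{k}", k
    # transcription order: on '-' the upstream gene has the larger start
    if b.strand == "-":
        canonical = b.start > c.start
    else:
        canonical = b.start < c.start
    return ("canonical" if canonical else "reversed"), 0


def _pair_cost(island: Island, b: GeneFeature, c: GeneFeature,
               bi: int, ci: int, n_c: int) -> float:
    cost = float(abs(intergenic_gap(b, c)))
    layout, _ = _layout(island, b, c)
    if layout == "reversed":
        cost += _REVERSED_PENALTY
    cost += _ORDER_PENALTY * (bi * n_c + ci)
    return cost


def pair_systems(
    island: Island, vocab: AliasVocabulary = DEFAULT_VOCAB
) -> list[PairedSystem]:
    """One-to-one B-C assignment minimizing summed genomic distance."""
    b_roles, c_roles = pair_candidates(island, vocab)
    if not b_roles or not c_roles:
        return []
    cost = np.array(
        [
            [_pair_cost(island, b, c, bi, ci, len(c_roles))
             for ci, c in enumerate(c_roles)]
            for bi, b in enumerate(b_roles)
        ]
    )
    rows, cols = linear_sum_assignment(cost)
    systems = []
    for n, (i, j) in enumerate(sorted(zip(rows, cols))):
        b, c = b_roles[i], c_roles[j]
        layout, k = _layout(island, b, c)
        systems.append(
            PairedSystem(
                system_id=f"{island.island_id}:sys{n}",
                mcrb_gene_id=b.gene_id,
                mcrc_gene_id=c.gene_id,
                layout=layout,
                gap_nt=intergenic_gap(b, c),
                island_id=island.island_id,
                low_confidence=(k > LOW_CONFIDENCE_INTERVENING),
            )
        )
    return systems


def report_orphans(
    islands: list[Island], vocab: AliasVocabulary = DEFAULT_VOCAB
) -> list[dict[str, object]]:
    """Role-carrying genes left unpaired, with their best evidence."""
    rows: list[dict[str, object]] = []
    for island in islands:
        b_roles, c_roles = pair_candidates(island, vocab)
        paired = {
            gid
            for s in pair_systems(island, vocab)
            for gid in (s.mcrb_gene_id, s.mcrc_gene_id)
        }
        for role, genes in (("McrB", b_roles), ("McrC", c_roles)):
            for gene in genes:
                if gene.gene_id in paired or not gene.annotations:
                    continue
                best = min(gene.annotations, key=lambda h: h.evalue)
                rows.append(
                    {
                        "island_id": island.island_id,
                        "gene_id": gene.gene_id,
                        "role": role,
                        "best_domain": best.domain_label,
                        "best_evalue": best.evalue,
                    }
                )
    return rows
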