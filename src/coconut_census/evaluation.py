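"""Scoring of census results against generator truth tables."""

from __future__ import annotations

from dataclasses import dataclass

from coconut_census.census import CensusResult
from coconut_census.synthetic import TruthRecord
from coconut_census.vocab import EXPECTED_CALL


@dataclass
class CohortScore:
    n_designed: int
    n_recovered: int
    n_subtype_correct: int
    n_decoys: int
    n_decoys_accepted: int
    per_genome_correct: dict[str, tuple[int, int]]

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_designed if self.n_designed else 1.0

    @property
    def subtype_accuracy(self) -> float:
        return (self.n_subtype_correct / self.n_designed
                if self.n_designed else 1.0)

    @property
    def decoy_acceptance(self) -> float:
        return (self.n_decoys_accepted / self.n_decoys
                if self.n_decoys else 0.0)


def score_cohort(result: CensusResult, truths: list[TruthRecord]) -> CohortScore:
    """Compare recovered, paired and typed systems against planted truth.

    A planted system counts as recovered when its McrB and McrC genes form
    one of the census's paired systems; its subtype call must equal the
    expected call for the planted subtype (classic NxxD McrBC maps to
    non-coconut).  A decoy is accepted if any of its genes ends up in a
    paired system.
    """
    by_pair = {(s.mcrb_gene_id, s.mcrc_gene_id): s for s in result.systems}
    accepted_genes = {g for s in result.systems
                      for g in (s.mcrb_gene_id, s.mcrc_gene_id)}
    n_designed = n_recovered = n_correct = 0
    n_decoys = n_decoys_accepted = 0
    per_genome: dict[str, list[int]] = {}
    for truth in truths:
        genome = truth.system_id.split("_")[0]
        if truth.subtype == "decoy":
            n_decoys += 1
            if set(truth.member_gene_ids) & accepted_genes:
                n_decoys_accepted += 1
            continue
        if truth.filter_design != "primary":
            continue  # rescue plants have no pairable second role
        n_designed += 1
        counts = per_genome.setdefault(genome, [0, 0])
        counts[1] += 1
        system = by_pair.get((truth.b_gene_id, truth.c_gene_id))
        if system is None:
            continue
        n_recovered += 1
        call = result.subtype_calls[system.system_id].subtype
        if call == EXPECTED_CALL[truth.subtype]:
            n_correct += 1
            counts[0] += 1
    return CohortScore(
        n_designed=n_designed,
        n_recovered=n_recovered,
        n_subtype_correct=n_correct,
        n_decoys=n_decoys,
        n_decoys_accepted=n_decoys_accepted,
        per_genome_correct={k: (v[0], v[1]) for k, v in per_genome.items()},
    )
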