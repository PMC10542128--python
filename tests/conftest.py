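"""Shared fixtures: small synthetic cohorts and truth-driven annotation."""

from __future__ import annotations

import numpy as np
import pytest

from coconut_census.genome_io import DomainHit, GenomeRecord
from coconut_census.synthetic import TruthRecord, generate_cohort


def annotate_from_truth(
    genomes: list[GenomeRecord], truths: list[TruthRecord]
) -> None:
    """Attach planted domain spans as DomainHits (bypassing profile search).

    Coiled-coil pseudo-domains are left out: the pipeline derives those
    from the coiled-coil predictor.
    """
    gene_map = {g.gene_id: g for genome in genomes for g in genome.genes}
    for truth in truths:
        for gene_id, design in truth.gene_designs.items():
            gene = gene_map.get(gene_id)
            if gene is None:  # gene dropped by the caller
                continue
            for label, start, end in design.domains:
                if label == "CC":
                    continue
                gene.annotations.append(
                    DomainHit(domain_label=label, start_aa=start, end_aa=end,
                              evalue=1e-12)
                )


@pytest.fixture(scope="session")
def small_cohort():
    """Three genomes, one system of each subtype + five decoys per genome."""
    return generate_cohort(3, seed=20260901)


@pytest.fixture()
def annotated_cohort():
    """Fresh copy of a small cohort with truth-derived domain annotations."""
    genomes, truths = generate_cohort(2, seed=7)
    annotate_from_truth(genomes, truths)
    return genomes, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
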