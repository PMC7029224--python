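"""Shared fixtures.

The expensive artefacts (a full synthetic community and its pipeline
runs, a 140 kb genome) are session-scoped; everything else is built
per-test at small sizes.
"""

from __future__ import annotations

import logging

import pytest

from pelagimine.pipeline import PipelineInputs, run_pipeline
from pelagimine.synthetic import GenomeParams, generate_community, generate_phage_genome

logging.getLogger("pelagimine").setLevel(logging.ERROR)


def community_inputs(com) -> PipelineInputs:
    return PipelineInputs(
        contigs=com.contigs,
        gene_calls=com.contig_genes,
        marker_refs_in=com.marker_refs_in,
        marker_refs_out=com.marker_refs_out,
        pmp_ref_proteins=com.pmp_ref_proteins,
        cmp_ref_proteins=com.cmp_ref_proteins,
    )


@pytest.fixture(scope="session")
def genome140():
    """One 140 kb genome with a 15 nt terminal repeat."""
    params = GenomeParams(length=140_000, gc=0.33, terminal_repeat=15)
    seq, truth = generate_phage_genome(params, seed=11, genome_id="g140")
    return seq, truth


@pytest.fixture(scope="session")
def genome30():
    """A small 30 kb genome for fast assembly/ANI tests."""
    params = GenomeParams(length=30_000, gc=0.33, terminal_repeat=15)
    seq, truth = generate_phage_genome(params, seed=7, genome_id="g30")
    return seq, truth


@pytest.fixture(scope="session")
def community_mut():
    """The study community: 3 targets + 3 decoys + background, shreds
    mutated at the 0.002 substitution rate."""
    return generate_community(seed=1)


@pytest.fixture(scope="session")
def community_exact():
    """Same design with error-free shreds (sub_rate 0)."""
    return generate_community(seed=1, shred_sub_rate=0.0)


@pytest.fixture(scope="session")
def pipeline_mut(community_mut):
    return run_pipeline(community_inputs(community_mut))


@pytest.fixture(scope="session")
def pipeline_exact(community_exact):
    return run_pipeline(community_inputs(community_exact))
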