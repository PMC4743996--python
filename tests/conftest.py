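"""Shared fixtures: one planted multi-genome collection and one full
pipeline run, built once per session (they are the expensive pieces)."""

from __future__ import annotations

import pytest

from rgenescape.pipeline import GenomeInput, run_pipeline
from rgenescape.synthetic_genome import default_fixture

FIXTURE_SEED = 1
PIPELINE_SEED = 3
# one reference-genome slot spans 8 kb in the bundled fixture, so a one-slot
# tolerance merges anchored intervals of the same planted locus only
MERGE_TOLERANCE = 8_000


@pytest.fixture(scope="session")
def collection():
    return default_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def pipeline_result(collection):
    inputs = [GenomeInput(g.genome_id, g.chromosomes, g.proteome, g.genes,
                          g.species)
              for g in collection.genomes]
    return run_pipeline(inputs, collection.vdb, collection.reference_id,
                        seed=PIPELINE_SEED, merge_tolerance=MERGE_TOLERANCE)


@pytest.fixture(scope="session")
def truth_genes(collection):
    return collection.combined_truth_genes().set_index("gene_id")
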