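"""Shared fixtures: the default simulated study and its pipeline runs.

The heavy end-to-end objects are session-scoped so the discovery flow,
placement flow and acceptance checks all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from afns.align import align, index_reference
from afns.pipeline import PipelineConfig, run_afns
from afns.placement import classify_sharing, place_sample
from afns.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The default study: 100 kb reference, 20 insertions, 2 samples,
    30x depth, 8% read error, 5% contaminant spike-in, seed 42."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def ref_index(default_sim):
    return index_reference(default_sim.reference, k=15)


@pytest.fixture(scope="session")
def pipeline_results(default_sim, ref_index):
    """run_afns per sample on the default study."""
    out = {}
    for sample in sorted(default_sim.reads):
        out[sample] = run_afns(
            default_sim.reads[sample],
            default_sim.reference,
            PipelineConfig(),
            read_calls=default_sim.kraken_calls[sample],
            taxonomy=default_sim.taxonomy,
            reference_index=ref_index,
        )
    return out


@pytest.fixture(scope="session")
def placement_clusters(default_sim, pipeline_results):
    """Surviving placement clusters per sample, reusing the pipeline's
    read-vs-reference alignments."""
    out = {}
    for sample, res in pipeline_results.items():
        out[sample] = place_sample(
            default_sim.reads[sample], res.read_alignments, sample
        )
    return out


@pytest.fixture(scope="session")
def labelled_clusters(default_sim, placement_clusters):
    pops = dict(default_sim.config.samples)
    classify_sharing(placement_clusters, pops)
    return placement_clusters


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
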