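"""Shared fixtures: a small seeded synthetic run and junction factories."""

from __future__ import annotations

import pytest

from splicescape import synthetic_data as sd
from splicescape.junction_catalog import SpliceJunction


def make_sj(chrom="chr1", strand="+", start=100, end=200, support=None, seq=""):
    return SpliceJunction(
        chrom=chrom,
        strand=strand,
        intron_start=start,
        intron_end=end,
        support=support or {"s1": 5},
        intron_seq=seq,
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic pipeline run under the default study conditions."""
    from splicescape.downstream_stats import run_pipeline

    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline({"mode": "synthetic", "seed": 11}, outdir)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset (shared, read-only)."""
    gspec = sd.GenomeSpec(seed=5, n_chroms=2, chrom_length=100_000)
    gene_spec = sd.GeneSpec(n_genes=25)
    genome, truth = sd.generate_genome(gspec, gene_spec)
    truth = sd.plant_events(truth, sd.EventSpec(), genome=genome)
    sim = sd.simulate_sequencing(truth, sd.ReadSimSpec(seed=5, junction_depth_mean=25))
    return truth.genome, truth, sim
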