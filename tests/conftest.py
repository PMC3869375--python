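import time

import pytest

from enact import (AnalysisConfig, SimConfig, run_pipeline,
                   simulate_annotation, write_fixtures)

TRUTH_KEYS = ("chrom_sizes", "annotation", "truth_elements", "truth_genes")


@pytest.fixture(scope="session")
def sim_config():
    """The default study conditions (seed 42)."""
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    return simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def fixture_manifest(tmp_path_factory, sim_config):
    """Complete synthetic fixture set written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(sim_config, outdir)


@pytest.fixture(scope="session")
def pipeline_run(fixture_manifest, tmp_path_factory):
    """One full end-to-end pipeline run on the default fixtures.

    Returns (summary, wall-clock seconds, output directory).
    """
    samples = {k: v for k, v in fixture_manifest.items() if k not in TRUTH_KEYS}
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = AnalysisConfig(
        chrom_sizes=fixture_manifest["chrom_sizes"],
        annotation=fixture_manifest["annotation"],
        samples=samples,
        output_dir=str(outdir),
    )
    t0 = time.monotonic()
    summary = run_pipeline(config)
    elapsed = time.monotonic() - t0
    return summary, elapsed, outdir
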