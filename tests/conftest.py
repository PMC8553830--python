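import pytest

from circfluid import FilterConfig, GeneratorConfig, run_pipeline, simulate_truth
from circfluid.junctions import TOOLS
from circfluid.simulate import emit_files

NO_NOISE = {t: 0.0 for t in TOOLS}

# the synthetic studies are an order of magnitude below the real cohort, so
# the sample-QC threshold scales with the catalog size
DEMO_FILTERS = FilterConfig(min_circ_per_sample=100)


@pytest.fixture(scope="session")
def noiseless_manifest():
    cfg = GeneratorConfig(dropout=dict(NO_NOISE), fp_rate=dict(NO_NOISE))
    return simulate_truth(cfg, seed=101)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_manifest, tmp_path_factory):
    out = tmp_path_factory.mktemp("noiseless_study")
    emit_files(noiseless_manifest, out)
    return out


@pytest.fixture(scope="session")
def noiseless_result(noiseless_study):
    return run_pipeline(noiseless_study, None, DEMO_FILTERS)


@pytest.fixture(scope="session")
def default_manifest():
    return simulate_truth(GeneratorConfig(), seed=11)


def retained_sets(manifest, fluid, min_reads=2, min_samples=5):
    """Per-tool retained sets straight from a manifest's tool counts."""
    return {
        tool: set(df.index[(df >= min_reads).sum(axis=1) >= min_samples])
        for tool, df in manifest.tool_counts[fluid].items()
    }
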