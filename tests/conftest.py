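import pytest

from sexscan import covscan as cov
from sexscan import synth
from sexscan.models import FixtureConfig


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig()


@pytest.fixture(scope="session")
def genes(default_config):
    return synth.build_fixture_genes(default_config)


@pytest.fixture(scope="session")
def cohort(default_config, genes):
    return synth.build_cohort(default_config, genes)


@pytest.fixture(scope="session")
def comparisons(cohort):
    raw = synth.windowed_tracks(cohort)
    norm = [cov.normalize_depth(t) for t in raw]
    return cov.compare_sexes(norm, raw)


@pytest.fixture(scope="session")
def expression_fixture(default_config, genes):
    return synth.build_expression_fixture(default_config, genes)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, default_config, genes):
    """Cohort written to disk once per session, for file-interface tests."""
    outdir = tmp_path_factory.mktemp("sim")
    synth.write_cohort(synth.build_cohort(default_config, genes), str(outdir))
    return outdir
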