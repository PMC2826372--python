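import warnings

import pytest

from phyexp.core_io import SpeciesMap


@pytest.fixture
def prefix_map():
    """Species resolution via the 'SPECIES|gene' prefix convention."""
    return SpeciesMap({}, None)


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    # NJ length clamping and non-monophyletic rooting warn by design;
    # keep test output readable without hiding unexpected warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="negative NJ branch lengths")
        yield


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory):
    """The standard miniature proteome (5 species, 50 families, seed 42,
    injected expansions 5/10/20) shared across pipeline-level tests."""
    from phyexp.synthetic_data import make_fixture_proteome

    path = tmp_path_factory.mktemp("fixture")
    truth = make_fixture_proteome(
        path, n_families=50, expansion_sizes=(5, 10, 20), seed=42
    )
    return path, truth


@pytest.fixture(scope="session")
def standard_run(standard_fixture, tmp_path_factory):
    """One completed pipeline run on the standard fixture."""
    from phyexp.pipeline import PipelineConfig, run_pipeline

    fix, truth = standard_fixture
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        proteins=str(fix / "proteins.faa"),
        cds=str(fix / "cds.fna"),
        species_map=str(fix / "species_map.tsv"),
        annotations=str(fix / "annotations.tsv"),
        seed=42,
        out_dir=str(out),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(cfg)
    return cfg, report, truth
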