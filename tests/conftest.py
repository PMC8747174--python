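import pytest

from mirprof.pipeline import make_study_bundle, run_pipeline


@pytest.fixture(scope="session")
def study():
    """A small synthetic study with planted conserved miRNAs and hairpins."""
    return make_study_bundle(seed=42, n_reads=3000, genome_length=25000, n_hairpins=3)


@pytest.fixture(scope="session")
def study_result(study):
    """The full pipeline run on the session study bundle."""
    return run_pipeline(study)


@pytest.fixture(scope="session")
def table2():
    from mirprof.seqio import load_table2_fixture

    return load_table2_fixture()


@pytest.fixture(scope="session")
def table3():
    from mirprof.seqio import load_table3_fixture

    return load_table3_fixture()
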