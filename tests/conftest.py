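import pytest

import hedkit as hk


@pytest.fixture(scope="session")
def base_schema():
    return hk.build_fixture_schema()


@pytest.fixture(scope="session")
def schemas(base_schema):
    return hk.SchemaSet(base_schema)


@pytest.fixture(scope="session")
def schemas_with_library(base_schema):
    return hk.merge_libraries(base_schema,
                              [("sc", hk.build_clinical_library())])


@pytest.fixture(scope="session")
def design1():
    """Generated Design-1 recording with its parsed inputs (2 blocks x 10)."""
    gen = hk.generate_design(hk.DesignSpec(design=1, seed=7))
    events = hk.read_events(gen.events_tsv)
    sidecar = hk.read_sidecar(gen.sidecar_json)
    defs, issues = hk.parse_definitions_file(gen.definitions_txt)
    assert not issues
    return gen, events, sidecar, defs


@pytest.fixture(scope="session")
def design1_assembled(design1, schemas):
    gen, events, sidecar, defs = design1
    assembled, defs, issues = hk.assemble(events, sidecar, schemas, defs)
    assert not [i for i in issues if i.severity == "error"]
    return gen, assembled, defs
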