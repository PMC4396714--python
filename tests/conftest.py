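import json
import os

import pytest

from termscout.fixtures import default_spec, generate
from termscout.pipeline import run_pipeline


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The standard seeded synthetic corpus pair + dictionary + manifest."""
    out = tmp_path_factory.mktemp("fixture")
    clin, bio, dic, man = generate(default_spec(seed=1), out)
    return {"clinical": clin, "biomedical": bio, "dictionary": dic, "manifest": man}


@pytest.fixture(scope="session")
def fixture_manifest(fixture_paths):
    with open(fixture_paths["manifest"], encoding="utf-8") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_result(fixture_paths, tmp_path_factory):
    """One full pipeline run over the standard fixture, shared by tests."""
    out = tmp_path_factory.mktemp("pipeline_out")
    result = run_pipeline(
        fixture_paths["clinical"],
        fixture_paths["biomedical"],
        fixture_paths["dictionary"],
        out,
    )
    return {"result": result, "out_dir": os.fspath(out)}
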