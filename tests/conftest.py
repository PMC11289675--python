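import json
from pathlib import Path

import pytest
from hypothesis import settings

from nemadesc.fixtures import PAPER_FIXTURES, make_paper_fixture
from nemadesc.pipeline import PipelineConfig, load_bundle, run_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dirs(tmp_path_factory) -> dict[str, Path]:
    """Each named fixture written out once per session."""
    root = tmp_path_factory.mktemp("paper_fixtures")
    dirs = {}
    for name in PAPER_FIXTURES:
        make_paper_fixture(name, root / name)
        dirs[name] = root / name
    return dirs


@pytest.fixture(scope="session")
def fixture_bundles(fixture_dirs):
    """Parsed AnnotationBundle per named fixture."""
    bundles = {}
    for name, directory in fixture_dirs.items():
        config = PipelineConfig.from_yaml(directory / "config.yaml")
        bundles[name] = load_bundle(config)
    return bundles


@pytest.fixture(scope="session")
def fixture_outputs(fixture_dirs):
    """Pipeline outputs (manifest + parsed summaries.json) per fixture."""
    outputs = {}
    for name, directory in fixture_dirs.items():
        manifest = run_pipeline(directory / "config.yaml")
        summaries = json.loads((directory / "out" / "summaries.json").read_text(encoding="utf-8"))
        outputs[name] = {"manifest": manifest, "summaries": summaries, "out_dir": directory / "out"}
    return outputs


def summary_text(outputs, name: str, gene_id: str) -> str:
    rows = {row["gene_id"]: row["description"] for row in outputs[name]["summaries"]}
    return rows[gene_id]
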