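import json
from pathlib import Path

import numpy as np
import pytest

from democlim import synthetic_data as syn
from democlim.pipeline import RunConfig


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory) -> dict:
    """A 12-population synthetic study with ground truth, written once."""
    out = tmp_path_factory.mktemp("demo") / "study"
    config = syn.make_ensemble(12, seed=7)
    paths = syn.generate_study(config, 7, out)
    truth = json.loads(Path(paths["truth"]).read_text())
    return {"paths": paths, "truth": truth, "config": config, "dir": out}


@pytest.fixture()
def demo_run_config(demo_study, tmp_path) -> RunConfig:
    paths = demo_study["paths"]
    return RunConfig(
        matrices_path=str(paths["matrices"]),
        climate_path=str(paths["climate"]),
        sites_path=str(paths["sites"]),
        populations_path=str(paths["populations"]),
        output_dir=str(tmp_path / "results"),
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
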