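import numpy as np
import pytest

from comfa.pipeline import RunConfig, run_pipeline
from comfa.registry import load_benzimidazole_dataset
from comfa.structures import Atom, Molecule


@pytest.fixture(scope="session")
def series():
    compounds, records = load_benzimidazole_dataset()
    return compounds, records


@pytest.fixture(scope="session")
def modelled_records(series):
    """The 29 records carrying pIC50 values (24 train + 5 test)."""
    _, records = series
    return [r for r in records if r.split in ("train", "test")]


@pytest.fixture(scope="session")
def pipeline_report():
    """One full deterministic pipeline run on the 29-compound series."""
    config = RunConfig(seed=2023, log_level="WARNING")
    return config, run_pipeline(config)


def make_molecule(coords, elements=None, charges=None, name="m"):
    coords = np.atleast_2d(np.asarray(coords, float))
    n = len(coords)
    elements = elements or ["C"] * n
    charges = charges if charges is not None else [0.0] * n
    atoms = [Atom(e, c, partial_charge=q) for e, c, q in zip(elements, coords, charges)]
    return Molecule(name, atoms)
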