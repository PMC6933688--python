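import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import herdimpute as hi
from herdimpute import benchmark
from herdimpute.simpop import AdmixtureSpec, BreedSpec


def tiny_config(seed: int = 11, **kw) -> hi.SimConfig:
    """Small three-breed panel for fast unit tests."""
    defaults = dict(
        n_markers=300,
        n_chromosomes=2,
        breeds=[
            BreedSpec("A", 80, 8, 0.10),
            BreedSpec("B", 40, 6, 0.12),
            BreedSpec("C", 30, 4, 0.10),
        ],
        admixed_samples=[
            AdmixtureSpec("X0", (("A", 0.5), ("B", 0.5))),
            AdmixtureSpec("X1", (("A", 0.5), ("C", 0.5))),
        ],
        seed=seed,
    )
    defaults.update(kw)
    return hi.SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_panel():
    return hi.simulate_panel(tiny_config())


@pytest.fixture(scope="session")
def tiny_assays(tiny_panel):
    specs = hi.default_assay_specs(tiny_panel.n_markers)
    return {a.name: a for a in hi.define_assays(tiny_panel, specs, seed=3)}


def make_matrix(calls, ids=None, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    mm = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": (np.arange(m) + 1) * 100,
            "id": [f"m{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )
    return hi.GenotypeMatrix(
        calls=calls,
        marker_map=mm,
        sample_ids=ids or [f"s{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def study():
    """The seeded desk-scale benchmark study (shared across heavy tests)."""
    return benchmark.build_study(seed=1)


@pytest.fixture(scope="session")
def study_sweep(study):
    return benchmark.density_sweep(study)
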