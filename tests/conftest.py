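import numpy as np
import pandas as pd
import pytest

from ldcohorts.io import GenotypeMatrix, MISSING
from ldcohorts.pipeline import run_pipeline
from ldcohorts.simulate import SimulationConfig, simulate

#: Suite-wide seed for everything stochastic.
SEED = 1


def make_matrix(dosages, scaffolds=None, positions=None, roles=None, groups=None):
    """Build a GenotypeMatrix around a raw dosage array with minimal metadata."""
    X = np.asarray(dosages, dtype=np.int8)
    n, p = X.shape
    scaffolds = scaffolds if scaffolds is not None else [f"sc{j:03d}" for j in range(p)]
    positions = positions if positions is not None else [100 + j for j in range(p)]
    loci = pd.DataFrame(
        {
            "locus_id": [f"{s}:{q}" for s, q in zip(scaffolds, positions)],
            "scaffold": scaffolds,
            "position": positions,
            "ref": ["A"] * p,
            "alt": ["G"] * p,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "role": roles if roles is not None else ["wild"] * n,
            "group": groups if groups is not None else [None] * n,
            "known_sex": ["unknown"] * n,
        }
    )
    return GenotypeMatrix(dosages=X, loci=loci, samples=samples)


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition simulation at the suite seed."""
    cfg = SimulationConfig(seed=SEED)
    gm, truth = simulate(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    """Full pipeline run on the default simulation (shared: it is the
    expensive object most end-to-end checks interrogate)."""
    _, gm, _ = default_sim
    return run_pipeline(gm)
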