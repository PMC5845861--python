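import numpy as np
import pandas as pd
import pytest

import clsqtl


@pytest.fixture(scope="session")
def yeast_map():
    """Genome-scale map: 16 chromosomes x 19 markers, 15 cM / 40.5 kb spacing."""
    return clsqtl.make_marker_map(16, 19, 15, 2700)


@pytest.fixture(scope="session")
def cross488(yeast_map):
    """One 488-segregant cross shared by read-only tests."""
    return clsqtl.simulate_cross(yeast_map, 488, seed=42)


def qtl_phenotype(cross, marker, h2, seed, baseline=0.0):
    """Phenotype with one additive QTL explaining h2 of the variance (env sd 1)."""
    a = 2.0 * np.sqrt(h2 / (1.0 - h2))
    rng = np.random.default_rng(seed)
    g = cross.genotypes[marker].to_numpy()
    g = np.where(np.isnan(g), 0.5, g)
    return pd.Series(
        baseline + a * g + rng.normal(0.0, 1.0, len(g)),
        index=cross.genotypes.index,
    )
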