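import numpy as np
import pandas as pd
import pytest

from xomap import ChromosomeSpec, GenotypeMatrix, tair10_chromosomes
from xomap.matrix import HET, HOM_COL, HOM_LER, MISSING


@pytest.fixture(scope="session")
def tair_specs():
    return tair10_chromosomes()


@pytest.fixture
def small_spec():
    """One 15-Mb chromosome with a uniform 60-cM map."""
    return ChromosomeSpec(
        name="chrS", length_bp=15_000_000, map_points=((1, 0.0), (15_000_000, 60.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


def make_matrix(calls, depths=None, positions=None, chrom="chr1", samples=None):
    """Build a GenotypeMatrix from a small 2D list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_m = calls.shape
    if depths is None:
        depths = np.full_like(calls, 10, dtype=np.int32)
    if positions is None:
        positions = np.arange(1, n_m + 1) * 1000
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_s)]
    markers = pd.DataFrame({"chrom": chrom, "pos": positions, "ref": "A", "alt": "C"})
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls, depth=np.asarray(depths, dtype=np.int32))
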