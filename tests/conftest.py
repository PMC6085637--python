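import numpy as np
import pytest
from hypothesis import settings

from consgen.io import GenotypeMatrix, VariantTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_gm(calls, positions=None, chrom="gga1", samples=None):
    """Build a GenotypeMatrix from a (samples x variants) array of codes."""
    calls = np.asarray(calls)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if isinstance(chrom, str):
        chrom = [chrom] * m
    vt = VariantTable(np.array(chrom, dtype=object), np.asarray(positions), ["A"] * m, ["G"] * m)
    return GenotypeMatrix(samples, vt, calls)


@pytest.fixture
def small_fixture():
    """Desk-scale nine-subpopulation study fixture (kept small for speed)."""
    import consgen as cg

    return cg.generate_study_fixture(11, genome=cg.default_genome(2, 200))
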