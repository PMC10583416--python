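import numpy as np
import pytest

from medimr.summaries import HarmonizedSet, SummaryStats, VariantAssociation


def va(vid, ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, pos=100, chrom="1",
       pval=1e-5, n=1000.0):
    """Shorthand VariantAssociation builder for tests."""
    return VariantAssociation(vid, chrom, pos, ea, oa, eaf, beta, se, pval, n)


def stats(records, name="trait", trait_type="quantitative"):
    return SummaryStats(name, trait_type, list(records))


def hset(bx, sx, by, sy, **kw):
    """HarmonizedSet from plain lists (single exposure)."""
    return HarmonizedSet.from_arrays(
        np.asarray(bx, float), np.asarray(sx, float),
        np.asarray(by, float), np.asarray(sy, float), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20230_17)


@pytest.fixture
def homogeneous_hset(rng):
    """10 instruments, true slope 0.5, no pleiotropy, seeded noise."""
    j = 10
    bx = rng.uniform(0.05, 0.15, j)
    sx = np.full(j, 0.004)
    sy = np.full(j, 0.02)
    by = 0.5 * bx + rng.normal(0, sy)
    return hset(bx, sx, by, sy)


def random_hset(rng, j=8, slope=0.3):
    bx = rng.uniform(0.03, 0.2, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.003, 0.01, j)
    sy = rng.uniform(0.01, 0.05, j)
    by = slope * bx + rng.normal(0, sy)
    return hset(bx, sx, by, sy)
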