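import numpy as np
import pytest

from setrcall.io_formats import SnpSite, TargetRegion, TargetSet


@pytest.fixture
def small_targets():
    """Ten 150 bp probes on one chromosome, 10 kb apart."""
    return TargetSet([
        TargetRegion("chr1", k * 10_000, k * 10_000 + 150, f"chr1_{k}", k)
        for k in range(10)
    ])


@pytest.fixture
def two_chrom_targets():
    """12 probes on chr1 + 8 on chr2."""
    regions = []
    i = 0
    for chrom, n in [("chr1", 12), ("chr2", 8)]:
        for k in range(n):
            regions.append(
                TargetRegion(chrom, k * 10_000, k * 10_000 + 150,
                             f"{chrom}_{k}", i))
            i += 1
    return TargetSet(regions)


@pytest.fixture
def small_sites(small_targets):
    return [
        SnpSite("chr1", r.start + 50, "A", "G", 0.5, f"chr1:{r.start + 50}")
        for r in small_targets
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
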