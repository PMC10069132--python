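import numpy as np
import pandas as pd
import pytest

from popscan.genio import GenotypeMatrix, HaplotypeSet, MarkerMap


def make_markers(n, chrom="1", spacing=50_000, start=1, a_minor="A", a_major="B"):
    return MarkerMap(pd.DataFrame({
        "chrom": str(chrom),
        "snp": [f"s{chrom}_{i}" for i in range(n)],
        "bp": start + spacing * np.arange(n),
        "a_minor": a_minor,
        "a_major": a_major,
    }))


def make_geno(geno, markers=None, pops=None, ids=None, **marker_kw):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    markers = markers if markers is not None else make_markers(m, **marker_kw)
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    pops = pops if pops is not None else ["pop1"] * n
    return GenotypeMatrix(geno, ids, pops, markers)


def make_haps(haps, markers=None, population="pop1", **marker_kw):
    haps = np.asarray(haps, dtype=np.int8)
    markers = markers if markers is not None else make_markers(haps.shape[1], **marker_kw)
    ids = [f"{population}_{i}" for i in range(haps.shape[0] // 2)]
    return HaplotypeSet(haps, ids, population, markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
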