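import numpy as np
import pytest

from sweepscan.panel import GenotypeMatrix, MarkerMap


def make_map(n, chrom="chr1", spacing=1000, start=1000):
    """Evenly spaced marker map on one or more chromosomes.

    ``chrom`` may be a single label or a list of per-marker labels.
    """
    if isinstance(chrom, str):
        chroms = [chrom] * n
    else:
        chroms = list(chrom)
    pos = []
    last = {}
    for c in chroms:
        last[c] = last.get(c, start - spacing) + spacing
        pos.append(last[c])
    return MarkerMap(
        np.array([f"m{i+1}" for i in range(n)], dtype=object),
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
    )


def make_panel(calls, pop="P1", markers=None):
    calls = np.asarray(calls, dtype=np.int8)
    if markers is None:
        markers = make_map(calls.shape[1])
    inds = tuple(f"{pop}_i{k+1}" for k in range(calls.shape[0]))
    return GenotypeMatrix(pop, inds, calls, markers)


@pytest.fixture
def tiny_map():
    return make_map(4)


@pytest.fixture
def tiny_panel(tiny_map):
    calls = np.array([
        [0, 2, 1, 0],
        [1, 2, -1, 0],
        [2, 1, 1, 0],
    ], dtype=np.int8)
    return make_panel(calls, "P1", tiny_map)
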