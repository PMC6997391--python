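import numpy as np
import pandas as pd
import pytest

from metacommunity.matrices import SAMPLE_KEY_FIELDS, AbundanceMatrix, IncidenceMatrix


def key_index(n, estuary="E1", period="P1", station_offset=0):
    return pd.MultiIndex.from_arrays(
        [
            [estuary] * n,
            [period] * n,
            [f"{i + 1 + station_offset:02d}" for i in range(n)],
            ["a"] * n,
        ],
        names=SAMPLE_KEY_FIELDS,
    )


def make_incidence(arr) -> IncidenceMatrix:
    arr = np.asarray(arr)
    return IncidenceMatrix(
        pd.DataFrame(arr, index=key_index(arr.shape[0]),
                     columns=[f"T{j + 1:03d}" for j in range(arr.shape[1])])
    )


def make_abundance(arr) -> AbundanceMatrix:
    arr = np.asarray(arr)
    return AbundanceMatrix(
        pd.DataFrame(arr, index=key_index(arr.shape[0]),
                     columns=[f"T{j + 1:03d}" for j in range(arr.shape[1])])
    )


@pytest.fixture
def staircase():
    """Perfectly nested triangular matrix (row i holds the i richest sets)."""
    n = 6
    return np.tril(np.ones((n, n), dtype=np.int8))[::-1]


def random_binary(rng, shape, fill=0.5, nonempty=True):
    while True:
        m = (rng.random(shape) < fill).astype(np.int8)
        if not nonempty or (m.sum(0).all() and m.sum(1).all()):
            return m


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_embedded_absences(m, axis="both"):
    m = np.asarray(m)
    total = 0
    for col in m.T:
        ones = [i for i, v in enumerate(col) if v]
        if ones:
            total += sum(1 for i in range(min(ones), max(ones) + 1) if not col[i])
    if axis == "both":
        for row in m:
            ones = [j for j, v in enumerate(row) if v]
            if ones:
                total += sum(1 for j in range(min(ones), max(ones) + 1) if not row[j])
    return total


def brute_replacements(m):
    m = np.asarray(m)
    n, s = m.shape
    count = 0
    for a in range(s):
        for b in range(a + 1, s):
            for i in range(n):
                for j in range(i + 1, n):
                    pat = (m[i, a], m[j, a], m[i, b], m[j, b])
                    if pat in ((1, 0, 0, 1), (0, 1, 1, 0)):
                        count += 1
    return count


def brute_nodf(m):
    """Naive NODF on the matrix as given (no sorting)."""
    m = np.asarray(m)

    def pair_sum(mm):
        tot, npairs = 0.0, 0
        for u in range(mm.shape[0]):
            for v in range(u + 1, mm.shape[0]):
                npairs += 1
                fu, fv = mm[u].sum(), mm[v].sum()
                if fu > fv and fv > 0:
                    shared = int((mm[u] & mm[v]).sum())
                    tot += 100.0 * shared / fv
        return tot, npairs

    rs, rp = pair_sum(m)
    cs, cp = pair_sum(m.T)
    return rs / rp, cs / cp, (rs + cs) / (rp + cp)
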