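"""Independent oracles used by the test suite (kept free of package internals)."""

import numpy as np


def morans_i(values: np.ndarray) -> float:
    """Moran's I with rook adjacency, computed directly from the definition."""
    z = values - values.mean()
    num = 0.0
    wsum = 0.0
    nrows, ncols = values.shape
    for dr, dc in ((0, 1), (1, 0)):
        a = z[: nrows - dr, : ncols - dc]
        b = z[dr:, dc:]
        num += 2.0 * float((a * b).sum())
        wsum += 2.0 * a.size
    return (values.size / wsum) * num / float((z**2).sum())


def dense_grid_solve(resistance: np.ndarray, source_cell, ground_cell):
    """Brute-force circuit solve on a full grid by dense linear algebra.

    Builds the graph Laplacian with explicit loops (4-neighbor lattice, edge
    resistance = mean of the two cell resistances), injects one unit of
    current at ``source_cell`` with ``ground_cell`` at 0 V, and solves with
    numpy. Returns the per-cell voltage array.
    """
    nrows, ncols = resistance.shape
    n = nrows * ncols
    L = np.zeros((n, n))
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr < nrows and cc < ncols:
                    j = rr * ncols + cc
                    g = 1.0 / ((resistance[r, c] + resistance[rr, cc]) / 2.0)
                    L[i, i] += g
                    L[j, j] += g
                    L[i, j] -= g
                    L[j, i] -= g
    s = source_cell[0] * ncols + source_cell[1]
    t = ground_cell[0] * ncols + ground_cell[1]
    b = np.zeros(n)
    b[s] = 1.0
    keep = [k for k in range(n) if k != t]
    v = np.zeros(n)
    v[keep] = np.linalg.solve(L[np.ix_(keep, keep)], b[keep])
    return v.reshape(nrows, ncols)
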