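"""Block-Hankel tensor transform of multi-coil k-space and its unfoldings.

A 4-D k-space tensor ``D`` of shape ``(Nkx, Nky, NRx, NTx)`` is mapped by the
linear operator ``T`` to a 4-D tensor ``H`` of shape ``(N1, N2, NRx, NTx)``
whose frontal slices ``H[:, :, r, t]`` are block-Hankel: column ``j`` is the
vectorised ``m x n`` k-space patch at the ``j``-th fully-interior kernel
placement, so

    N1 = m * n
    N2 = (Nkx - m + 1) * (Nky - n + 1)

Ordering convention (frozen; every unfolding depends on it): both kernel
placements and within-kernel offsets are enumerated in C (row-major) order
over ``(kx, ky)``, i.e. the ky offset varies fastest.  Only fully-interior
placements are used — there is no wrap-around or zero padding.

Three matricisations of ``H`` expose different low-rank structure:

``VC``
    virtual-coil unfolding, ``(N1*NRx*NTx, N2)`` — every (receive, transmit)
    pair treated as an independent virtual receive coil.
``RC``
    receive concatenation, ``(N1*NRx, N2*NTx)`` — receive channels stacked
    vertically, transmit encodings horizontally (the PRIMO-style calibration
    matrix).
``TC``
    transmit concatenation, ``(N1*NTx, N2*NRx)`` — the symmetric counterpart
    with the roles of transmit and receive swapped.  Because the frontal
    slices themselves are unchanged by the swap, ``TC`` is *not* the
    transpose of ``RC``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "hankel_shape",
    "build_hankel_tensor",
    "adjoint_hankel",
    "multiplicity_map",
    "unfold",
    "fold",
    "UNFOLDINGS",
]

UNFOLDINGS = ("VC", "RC", "TC")


def _check_kernel(grid: tuple[int, int], kernel: tuple[int, int]) -> None:
    nkx, nky = grid
    m, n = kernel
    if m < 1 or n < 1:
        raise ValueError(f"kernel dimensions must be positive, got {kernel}")
    if m > nkx or n > nky:
        raise ValueError(
            f"kernel {kernel} does not fit inside k-space grid {grid}"
        )


def hankel_shape(grid: tuple[int, int], kernel: tuple[int, int]) -> tuple[int, int]:
    """Return ``(N1, N2)`` for a grid and kernel size.

    ``N1 = m*n`` rows per coil block and ``N2 = (Nkx-m+1)*(Nky-n+1)``
    fully-interior kernel placements.
    """
    _check_kernel(grid, kernel)
    nkx, nky = grid
    m, n = kernel
    return m * n, (nkx - m + 1) * (nky - n + 1)


def build_hankel_tensor(data: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Apply the Hankel transform ``T`` to a k-space tensor.

    Parameters
    ----------
    data
        Complex array ``(Nkx, Nky, NRx, NTx)``.
    kernel
        ``(m, n)`` kernel extent in kx and ky.

    Returns
    -------
    ndarray
        ``(N1, N2, NRx, NTx)`` tensor with block-Hankel frontal slices.
    """
    if data.ndim != 4:
        raise ValueError(f"expected 4-D (kx, ky, rx, tx) array, got ndim={data.ndim}")
    nkx, nky, nrx, ntx = data.shape
    _check_kernel((nkx, nky), kernel)
    m, n = kernel
    # windows: (Px, Py, NRx, NTx, m, n) with Px = Nkx-m+1, Py = Nky-n+1
    windows = sliding_window_view(data, (m, n), axis=(0, 1))
    px, py = windows.shape[0], windows.shape[1]
    h = windows.transpose(4, 5, 0, 1, 2, 3).reshape(m * n, px * py, nrx, ntx)
    return np.ascontiguousarray(h)


def adjoint_hankel(
    h: np.ndarray, grid: tuple[int, int], kernel: tuple[int, int]
) -> np.ndarray:
    """Apply the adjoint ``T*``: accumulate Hankel entries back onto k-space.

    Each k-space location receives the *sum* of every Hankel-tensor entry
    that maps to it (unnormalised adjoint, not an average), so
    ``T*(T(D)) = multiplicity_map(...) * D`` elementwise.
    """
    nkx, nky = grid
    _check_kernel(grid, kernel)
    m, n = kernel
    px, py = nkx - m + 1, nky - n + 1
    n1, n2 = m * n, px * py
    if h.ndim != 4 or h.shape[0] != n1 or h.shape[1] != n2:
        raise ValueError(
            f"Hankel tensor shape {h.shape} inconsistent with grid {grid} "
            f"and kernel {kernel} (expected leading dims ({n1}, {n2}))"
        )
    nrx, ntx = h.shape[2], h.shape[3]
    hr = h.reshape(m, n, px, py, nrx, ntx)
    out = np.zeros((nkx, nky, nrx, ntx), dtype=h.dtype)
    for ix in range(m):
        for iy in range(n):
            out[ix : ix + px, iy : iy + py] += hr[ix, iy]
    return out


def multiplicity_map(grid: tuple[int, int], kernel: tuple[int, int]) -> np.ndarray:
    """Number of kernel placements covering each k-space location.

    This is the diagonal of ``T*T``; entries lie in ``[1, m*n]`` and sum to
    ``N1 * N2``.  Needed for the closed-form data-consistency update.
    """
    _check_kernel(grid, kernel)
    nkx, nky = grid
    m, n = kernel
    wx = np.convolve(np.ones(nkx - m + 1, dtype=np.int64), np.ones(m, dtype=np.int64))
    wy = np.convolve(np.ones(nky - n + 1, dtype=np.int64), np.ones(n, dtype=np.int64))
    return np.outer(wx, wy)


# Axis permutations taking (N1, N2, NRx, NTx) to the row/column block layout
# of each unfolding; rows are the first group, columns the second.
_PERMS = {
    "VC": ((2, 3, 0), (1,)),  # rows (rx, tx, N1), cols (N2)
    "RC": ((2, 0), (3, 1)),   # rows (rx, N1),     cols (tx, N2)
    "TC": ((3, 0), (2, 1)),   # rows (tx, N1),     cols (rx, N2)
}


def unfold(h: np.ndarray, tag: str) -> np.ndarray:
    """Matricise a Hankel tensor according to one of the three unfoldings."""
    if tag not in _PERMS:
        raise ValueError(f"unknown unfolding {tag!r}; expected one of {UNFOLDINGS}")
    rows, cols = _PERMS[tag]
    perm = rows + cols
    t = h.transpose(perm)
    nrow = int(np.prod([h.shape[a] for a in rows]))
    ncol = int(np.prod([h.shape[a] for a in cols]))
    return t.reshape(nrow, ncol)


def fold(mat: np.ndarray, dims: tuple[int, int, int, int], tag: str) -> np.ndarray:
    """Exact inverse of :func:`unfold` back to ``(N1, N2, NRx, NTx)``."""
    if tag not in _PERMS:
        raise ValueError(f"unknown unfolding {tag!r}; expected one of {UNFOLDINGS}")
    rows, cols = _PERMS[tag]
    perm = rows + cols
    expected = (
        int(np.prod([dims[a] for a in rows])),
        int(np.prod([dims[a] for a in cols])),
    )
    if mat.shape != expected:
        raise ValueError(
            f"matrix shape {mat.shape} does not match {tag} unfolding of dims "
            f"{dims} (expected {expected})"
        )
    t = mat.reshape(tuple(dims[a] for a in perm))
    inv = np.argsort(perm)
    return np.ascontiguousarray(t.transpose(tuple(inv)))
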