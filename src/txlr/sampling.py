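"""Poisson-disc k-space undersampling masks.

One binary pattern per transmit encoding, shared across receive channels.
Patterns are uniform-density pseudo-random Poisson disc: greedy dart
throwing with a minimum pairwise distance, the radius tuned by bisection so
the sampled fraction matches the nominal acceleration ``R`` (achieved
acceleration exact after trimming, always within 5% of ``R``).

Conventions (frozen, shared with the synthetic and solver modules):

* the DC sample at index ``(Nkx//2, Nky//2)`` (FFT-shifted layout) is always
  sampled in every encoding — relative scaling between encodings is lost
  without it;
* each transmit encoding draws from an independent child of the master seed,
  so patterns differ across encodings but the whole mask is reproducible
  from one integer;
* there is no fully sampled calibration region — the reconstruction is
  calibrationless by design.
"""

from __future__ import annotations

import numpy as np

__all__ = ["poisson_disc_mask"]


def _greedy_disc(order: np.ndarray, coords: np.ndarray, radius: float) -> np.ndarray:
    """Indices (into ``coords``) accepted by greedy dart throwing at ``radius``."""
    accepted: list[int] = []
    acc_xy = np.empty((0, 2), dtype=np.float64)
    r2 = radius * radius
    for idx in order:
        p = coords[idx]
        if acc_xy.size:
            d2 = ((acc_xy - p) ** 2).sum(axis=1)
            if d2.min() < r2:
                continue
        accepted.append(idx)
        acc_xy = np.vstack([acc_xy, p[None, :]])
    return np.asarray(accepted, dtype=np.int64)


def _single_mask(
    nkx: int, nky: int, target: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    total = nkx * nky
    coords = np.stack(
        np.meshgrid(np.arange(nkx), np.arange(nky), indexing="ij"), axis=-1
    ).reshape(total, 2).astype(np.float64)
    dc = (nkx // 2) * nky + (nky // 2)
    rest = rng.permutation(np.delete(np.arange(total), dc))
    order = np.concatenate([[dc], rest])

    if target >= total:
        return np.ones((nkx, nky), dtype=np.uint8), 0.0

    # Bisect for the largest radius whose greedy pattern still reaches the
    # target count, then trim the tail of the acceptance order down to the
    # target; trimming preserves the minimum-distance property.
    lo, hi = 0.999, float(np.hypot(nkx, nky))
    if len(_greedy_disc(order, coords, hi)) >= target:
        lo = hi
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if len(_greedy_disc(order, coords, mid)) >= target:
                lo = mid
            else:
                hi = mid
    accepted = _greedy_disc(order, coords, lo)[:target]
    mask = np.zeros((nkx, nky), dtype=np.uint8)
    mask.flat[accepted] = 1
    return mask, lo


def poisson_disc_mask(
    nkx: int,
    nky: int,
    ntx: int,
    R: float,
    seed: int,
    full_output: bool = False,
):
    """Generate per-transmit-encoding Poisson-disc sampling masks.

    Parameters
    ----------
    nkx, nky
        k-space grid dimensions.
    ntx
        Number of transmit encodings (one pattern each).
    R
        Nominal acceleration factor; the sampled fraction per encoding is
        ``round(nkx*nky/R)`` points, within 5% of ``1/R``.
    seed
        Master seed; each encoding uses an independent spawned child.
    full_output
        If True also return the tuned minimum-distance radius per encoding.

    Returns
    -------
    mask : ndarray of uint8, shape ``(nkx, nky, ntx)``
        Binary sampling mask (1 = sampled), DC always sampled.
    radii : ndarray of float, shape ``(ntx,)``, only if ``full_output``.
    """
    total = nkx * nky
    if R < 1 or R > total:
        raise ValueError(
            f"acceleration R={R} out of range; feasible range is [1, {total}]"
        )
    target = int(round(total / R))
    if target < 1 or abs(target * R - total) / total > 0.05 * 1.0:
        # target quantisation alone must not break the 5% contract
        raise ValueError(
            f"R={R} unreachable on a {nkx}x{nky} grid: nearest achievable "
            f"fraction {target/total:.4f} deviates >5% from 1/R={1/R:.4f}"
        )
    children = np.random.SeedSequence(seed).spawn(ntx)
    mask = np.empty((nkx, nky, ntx), dtype=np.uint8)
    radii = np.empty(ntx)
    for t in range(ntx):
        mask[:, :, t], radii[t] = _single_mask(
            nkx, nky, target, np.random.default_rng(children[t])
        )
    if full_output:
        return mask, radii
    return mask
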