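"""Relative transmit (and receive) sensitivity map extraction.

After k-space completion, each voxel carries an ``NRx x NTx`` matrix of
per-channel-pair image values.  Under the separable signal model that
matrix is rank one — (receive vector) x (transmit vector) scaled by the
local proton density — so its dominant right singular vector is the
relative transmit sensitivity and the dominant left singular vector the
relative receive sensitivity.  Relative maps are defined only up to a
common per-voxel complex factor; we fix the gauge by normalising each
voxel's channel vector to unit root-sum-of-squares and subtracting the
phase of channel 1 from all channels.

Voxels whose total signal falls below 5% of the image maximum are outside
the support mask: relative mapping is meaningless where there is no signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensitivityMaps", "estimate_relative_maps", "normalize_maps", "map_error"]


@dataclass
class SensitivityMaps:
    """Relative per-channel sensitivities on a support mask.

    ``tx``: complex ``(Nx, Ny, NTx)``; ``rx``: complex ``(Nx, Ny, NRx)`` or
    None; ``support``: bool ``(Nx, Ny)``.  On support each voxel's channel
    vector has unit RSS and zero phase on channel 1; off support maps are 0.
    """

    tx: np.ndarray
    rx: np.ndarray | None
    support: np.ndarray


def _gauge(v: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Unit-RSS normalisation and channel-1 phase referencing per voxel."""
    out = np.zeros_like(v)
    nrm = np.linalg.norm(v, axis=-1)
    ok = support & (nrm > 0)
    out[ok] = v[ok] / nrm[ok, None]
    ref = out[..., 0]
    phase = np.ones_like(ref)
    nz = ok & (np.abs(ref) > 0)
    phase[nz] = ref[nz] / np.abs(ref[nz])
    return out * np.conj(phase)[..., None]


def normalize_maps(
    channels: np.ndarray, support: np.ndarray | None = None
) -> SensitivityMaps:
    """Bring a raw ``(Nx, Ny, Nc)`` profile stack into the map gauge.

    Used to put ground-truth transmit profiles on the same footing as
    estimated maps (unit RSS per voxel, channel-1 phase reference).
    """
    channels = np.asarray(channels)
    if support is None:
        support = np.linalg.norm(channels, axis=-1) > 0
    return SensitivityMaps(tx=_gauge(channels, support), rx=None, support=support)


def estimate_relative_maps(
    z: np.ndarray, support_frac: float = 0.05
) -> SensitivityMaps:
    """Extract relative transmit and receive maps from completed k-space.

    Each (receive, transmit) channel pair of ``z`` is inverse Fourier
    transformed to image space; the per-voxel ``NRx x NTx`` matrix is
    factorised by SVD and its dominant singular vectors give the relative
    maps.  Voxels with Frobenius signal below ``support_frac`` of the
    maximum are masked out (all-zero voxels are masked, never an error).
    Multiplying all images at a voxel by any nonzero complex scalar leaves
    the extracted transmit map unchanged.
    """
    if z.ndim != 4:
        raise ValueError("expected a (kx, ky, rx, tx) tensor")
    images = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(z, axes=(0, 1)), axes=(0, 1)), axes=(0, 1)
    )
    nx, ny, nrx, ntx = images.shape
    mag = np.linalg.norm(images.reshape(nx, ny, -1), axis=-1)
    peak = mag.max()
    support = mag >= support_frac * peak if peak > 0 else np.zeros_like(mag, bool)

    a = images.reshape(nx * ny, nrx, ntx)
    # A = f * (rx vector) (tx vector)^T per voxel, so the top row-space
    # vector vh[0] is the transmit channel vector (up to a phase fixed by
    # the gauge below) and the top left singular vector the receive one.
    u, s, vh = np.linalg.svd(a, full_matrices=False)
    tx = vh[:, 0, :].reshape(nx, ny, ntx)
    rx = u[:, :, 0].reshape(nx, ny, nrx)
    return SensitivityMaps(
        tx=_gauge(tx, support), rx=_gauge(rx, support), support=support
    )


def map_error(
    est: SensitivityMaps, truth: SensitivityMaps
) -> tuple[np.ndarray, float]:
    """Per-voxel complex map deviation and the complex RMSE over support.

    Returns ``(diff, rmse)`` where ``diff`` is the complex deviation
    magnitude per voxel and channel (zero off the joint support) and
    ``rmse`` is the root mean square of the deviations over the joint
    support and all channels.

    Relative maps are equivalence classes up to a common per-voxel complex
    phase, and the channel-1 phase reference becomes arbitrary at voxels
    where channel 1 has a sensitivity null.  The deviation is therefore
    computed after aligning the remaining free gauge: at each voxel the
    estimate is rotated by the common phase that best matches the truth
    before differencing.  For maps with a well-defined channel-1 reference
    this alignment is a no-op; a global phase on either input never
    contributes to the error.
    """
    if est.tx.shape != truth.tx.shape:
        raise ValueError(
            f"map shapes differ: {est.tx.shape} vs {truth.tx.shape}"
        )
    joint = est.support & truth.support
    inner = (np.conj(truth.tx) * est.tx).sum(axis=-1)
    mag = np.abs(inner)
    phase = np.where(mag > 0, inner / np.where(mag > 0, mag, 1.0), 1.0)
    diff = np.abs(est.tx * np.conj(phase)[..., None] - truth.tx) * joint[..., None]
    if not joint.any():
        return diff, 0.0
    rmse = float(np.sqrt((diff[joint] ** 2).mean()))
    return diff, rmse
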