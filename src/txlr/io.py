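"""HDF5 container for multi-transmit k-space datasets, plus NIfTI map export.

Layout (complex arrays stored as native HDF5 compound complex):

    /kspace          complex [Nkx, Nky, NRx, NTx]   (mandatory)
    /mask            uint8   [Nkx, Nky, NTx]
    /noise_sd        float   [NRx]
    /truth/kspace    complex [Nkx, Nky, NRx, NTx]
    /truth/tx_maps   complex [Nx, Ny, NTx]
    /truth/rx_maps   complex [Nx, Ny, NRx]
    /phantom         float   [Nx, Ny]

Root attributes: ``crop``, ``seed``, ``psnr_db``, ``version`` (all
optional).  Reads and writes are lossless round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Container", "SchemaError", "read_container", "write_container", "export_maps_nifti"]

FORMAT_VERSION = "1"


class SchemaError(ValueError):
    """Container does not conform to the expected layout."""


@dataclass
class Container:
    kspace: np.ndarray
    mask: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    truth_kspace: np.ndarray | None = None
    truth_tx_maps: np.ndarray | None = None
    truth_rx_maps: np.ndarray | None = None
    phantom: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)


_OPTIONAL = {
    "mask": "mask",
    "noise_sd": "noise_sd",
    "truth/kspace": "truth_kspace",
    "truth/tx_maps": "truth_tx_maps",
    "truth/rx_maps": "truth_rx_maps",
    "phantom": "phantom",
}


def write_container(path, c: Container) -> None:
    """Write a :class:`Container` to ``path`` (shapes validated first)."""
    _validate(c)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(c.kspace, dtype=np.complex128))
        for dset, attr in _OPTIONAL.items():
            val = getattr(c, attr)
            if val is not None:
                f.create_dataset(dset, data=np.asarray(val))
        for k, v in c.attrs.items():
            f.attrs[k] = v
        f.attrs.setdefault("version", FORMAT_VERSION)


def read_container(path) -> Container:
    """Read a container; missing mandatory datasets raise :class:`SchemaError`."""
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise SchemaError(f"{path}: missing mandatory dataset /kspace")
        c = Container(kspace=f["kspace"][()], attrs=dict(f.attrs))
        for dset, attr in _OPTIONAL.items():
            if dset in f:
                setattr(c, attr, f[dset][()])
    _validate(c)
    return c


def _validate(c: Container) -> None:
    k = np.asarray(c.kspace)
    if k.ndim != 4:
        raise SchemaError(f"/kspace must be 4-D (kx, ky, rx, tx), got {k.shape}")
    nkx, nky, nrx, ntx = k.shape
    if c.mask is not None:
        m = np.asarray(c.mask)
        if m.shape != (nkx, nky, ntx):
            raise SchemaError(
                f"/mask shape {m.shape} inconsistent with /kspace {k.shape}"
            )
        if not np.isin(m, (0, 1)).all():
            raise SchemaError("/mask must be binary")
    if c.noise_sd is not None and np.asarray(c.noise_sd).shape != (nrx,):
        raise SchemaError(f"/noise_sd must have shape ({nrx},)")
    if c.truth_kspace is not None and np.asarray(c.truth_kspace).shape != k.shape:
        raise SchemaError("/truth/kspace shape differs from /kspace")


def export_maps_nifti(maps, prefix: str) -> list[str]:
    """Write magnitude and phase NIfTI volumes for a set of relative maps.

    ``maps`` is a :class:`txlr.maps.SensitivityMaps`; files are written as
    ``<prefix>_tx_mag.nii.gz`` etc. with an identity affine (the synthetic
    grid has no physical orientation).  Returns the written paths.
    """
    import nibabel as nib

    written = []
    for name, arr in (("tx", maps.tx), ("rx", maps.rx)):
        if arr is None:
            continue
        for part, data in (("mag", np.abs(arr)), ("phase", np.angle(arr))):
            p = f"{prefix}_{name}_{part}.nii.gz"
            nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), p)
            written.append(p)
    return written
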