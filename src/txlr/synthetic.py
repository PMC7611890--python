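"""Synthetic multi-transmit / multi-receive k-space data.

Everything here emulates a body-imaging field-mapping acquisition so the
reconstruction can be exercised without scanner data: a digital torso-like
phantom whose pixel intensity is the tissue mass density (bone and lung
clamped to a fixed display value so the image resembles a proton-density
MR image), smooth analytic complex coil profiles standing in for full-wave
electromagnetic field simulations, and the exactly separable image model

    I[x, y, r, t] = phantom[x, y] * S_rx[x, y, r] * S_tx[x, y, t]

Fourier transformed per channel pair and centre-cropped to a small k-space
matrix.  Separability makes the receive- and transmit-concatenated Hankel
unfoldings numerically low rank — the structural property the reconstruction
exploits.  Complex circular Gaussian noise is added at a stated peak SNR,
quoted in dB as an amplitude ratio (max |k-space| over noise SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solver import NoiseModel

__all__ = [
    "Phantom",
    "CoilProfileSet",
    "generate_phantom",
    "generate_sensitivities",
    "simulate_kspace",
    "add_noise",
    "make_dataset",
]

#: densities > 1200 (bone) or < 400 (lung) are displayed at this intensity
CLAMP_VALUE = 80.0
DENSITY_HIGH = 1200.0
DENSITY_LOW = 400.0


@dataclass
class Phantom:
    """Digital density phantom: image, tissue-class labels, class densities."""

    image: np.ndarray  # real, non-negative [Nx, Ny]
    labels: np.ndarray  # int class labels [Nx, Ny]; 0 = air background
    densities: dict[int, float] = field(default_factory=dict)  # kg/m^3 per class


@dataclass
class CoilProfileSet:
    """Complex per-channel sensitivity profiles [Nx, Ny, Nc]."""

    profiles: np.ndarray
    kind: str
    seed: int

    @property
    def nc(self) -> int:
        return self.profiles.shape[2]


def _ellipse(nx, ny, cx, cy, ax, ay, angle=0.0):
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xr = (x - cx) * np.cos(angle) + (y - cy) * np.sin(angle)
    yr = -(x - cx) * np.sin(angle) + (y - cy) * np.cos(angle)
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def generate_phantom(nx: int, ny: int, seed: int = 0) -> Phantom:
    """Torso-like density phantom with lungs, spine, heart and liver.

    Tissue classes span the clamping rule: lung (300 kg/m^3 < 400) and
    cortical bone (1900 kg/m^3 > 1200) render at intensity 80, soft tissues
    at their density.  Organ positions are jittered slightly per seed so
    independent slices differ.  Air background (label 0) has zero intensity.
    """
    if nx < 8 or ny < 8:
        raise ValueError("phantom grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    j = lambda s: 1.0 + s * (rng.random() - 0.5)  # noqa: E731 small jitter

    labels = np.zeros((nx, ny), dtype=np.int64)
    cx, cy = nx / 2, ny / 2
    body = _ellipse(nx, ny, cx, cy, 0.44 * nx * j(0.05), 0.47 * ny * j(0.05))
    labels[body] = 1  # muscle
    for sx, lbl in ((-1, 2), (1, 2)):  # two lungs
        labels[
            _ellipse(
                nx, ny,
                cx + sx * 0.22 * nx * j(0.1), cy - 0.08 * ny * j(0.1),
                0.13 * nx * j(0.1), 0.22 * ny * j(0.1),
            )
            & body
        ] = lbl
    labels[  # heart between the lungs
        _ellipse(nx, ny, cx - 0.02 * nx, cy + 0.02 * ny * j(0.2),
                 0.11 * nx * j(0.1), 0.12 * ny * j(0.1), angle=0.4)
        & body
    ] = 3
    labels[  # liver, inferior-lateral blob
        _ellipse(nx, ny, cx + 0.16 * nx * j(0.1), cy + 0.26 * ny * j(0.1),
                 0.16 * nx * j(0.1), 0.13 * ny * j(0.1))
        & body
    ] = 4
    labels[  # spine / vertebral bone, posterior midline
        _ellipse(nx, ny, cx, cy - 0.36 * ny * j(0.05),
                 0.07 * nx * j(0.1), 0.06 * ny * j(0.1))
        & body
    ] = 5
    labels[  # fluid pocket, exercises an exactly-1000 soft class
        _ellipse(nx, ny, cx - 0.25 * nx * j(0.1), cy + 0.28 * ny * j(0.1),
                 0.05 * nx, 0.05 * ny)
        & body
    ] = 6

    densities = {1: 1090.0, 2: 300.0, 3: 1060.0, 4: 1060.0, 5: 1900.0, 6: 1000.0}
    image = np.zeros((nx, ny))
    for lbl, rho in densities.items():
        val = CLAMP_VALUE if (rho > DENSITY_HIGH or rho < DENSITY_LOW) else rho
        image[labels == lbl] = val
    return Phantom(image=image, labels=labels, densities=densities)


def _support_ellipse(nx: int, ny: int) -> np.ndarray:
    return _ellipse(nx, ny, nx / 2, ny / 2, 0.4 * nx, 0.4 * ny)


def generate_sensitivities(
    nx: int, ny: int, nc: int, kind: str = "gaussian", seed: int = 0
) -> CoilProfileSet:
    """Smooth complex coil profiles for ``nc`` channels ringing the FOV.

    ``gaussian``: complex Gaussian amplitude lobes centred just outside the
    FOV edge with a smooth low-order polynomial phase per channel.
    ``loop``: Lorentzian-type falloff ``h^2 / (d^2 + h^2)`` from a loop
    centre, a crude surface-coil model.  ``constant``: uniform unit profile.

    Profiles are normalised so the root-sum-of-squares over channels has
    mean 1 over the central elliptical support.  Each channel has distinct
    centre and phase coefficients, so the stacked profiles are linearly
    independent, and all profiles are bandlimited well below a 24-sample
    k-space crop.
    """
    if nc < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xh, yh = (x - nx / 2) / nx, (y - ny / 2) / ny  # in [-1/2, 1/2)

    if kind == "constant":
        prof = np.ones((nx, ny, nc), dtype=np.complex128)
        return CoilProfileSet(profiles=prof, kind=kind, seed=seed)

    prof = np.empty((nx, ny, nc), dtype=np.complex128)
    angles = 2 * np.pi * (np.arange(nc) + rng.random()) / nc
    for c in range(nc):
        # coil centre on a ring at ~0.55 FOV radius (just outside the body)
        ccx = 0.55 * np.cos(angles[c]) + 0.03 * (rng.random() - 0.5)
        ccy = 0.55 * np.sin(angles[c]) + 0.03 * (rng.random() - 0.5)
        d2 = (xh - ccx) ** 2 + (yh - ccy) ** 2
        if kind == "gaussian":
            w = 0.35 * (1 + 0.2 * (rng.random() - 0.5))
            amp = np.exp(-d2 / (2 * w * w))
        elif kind == "loop":
            h = 0.30 * (1 + 0.2 * (rng.random() - 0.5))
            amp = h * h / (d2 + h * h)
        else:
            raise ValueError(f"unknown profile kind {kind!r}")
        # smooth phase: propagation-like gradient away from the coil plus a
        # mild random low-order polynomial (kept small => bandlimited)
        a, b, cc, dd = rng.uniform(-1, 1, 4)
        phase = (
            2.0 * np.sqrt(d2)
            + a * xh + b * yh + cc * xh * yh + 0.5 * dd * (xh**2 - yh**2)
        )
        prof[:, :, c] = amp * np.exp(1j * 2 * np.pi * phase / 3.0)

    rss = np.sqrt((np.abs(prof) ** 2).sum(axis=2))
    prof /= rss[_support_ellipse(nx, ny)].mean()
    return CoilProfileSet(profiles=prof, kind=kind, seed=seed)


def _centered_fft2(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(0, 1)), axes=(0, 1)), axes=(0, 1)
    )


def simulate_kspace(
    phantom: Phantom | np.ndarray,
    tx: CoilProfileSet | np.ndarray,
    rx: CoilProfileSet | np.ndarray,
    crop: tuple[int, int] = (24, 24),
) -> np.ndarray:
    """Form the noiseless k-space tensor ``(ckx, cky, NRx, NTx)``.

    For each channel pair the image ``phantom * S_rx[r] * S_tx[t]`` is
    Fourier transformed (DC at index ``N//2``) and centre-cropped to
    ``crop``.  Cropping implicitly bandlimits the sensitivities, mirroring
    why a small central k-space matrix suffices to capture the dominant
    transmit modes.
    """
    img = phantom.image if isinstance(phantom, Phantom) else np.asarray(phantom)
    stx = tx.profiles if isinstance(tx, CoilProfileSet) else np.asarray(tx)
    srx = rx.profiles if isinstance(rx, CoilProfileSet) else np.asarray(rx)
    nx, ny = img.shape
    if stx.shape[:2] != (nx, ny) or srx.shape[:2] != (nx, ny):
        raise ValueError("phantom and sensitivity grids do not match")
    ckx, cky = crop
    if ckx > nx or cky > ny:
        raise ValueError(f"crop {crop} larger than grid {(nx, ny)}")
    images = img[:, :, None, None] * srx[:, :, :, None] * stx[:, :, None, :]
    ksp = _centered_fft2(images)
    sx, sy = nx // 2 - ckx // 2, ny // 2 - cky // 2
    return np.ascontiguousarray(ksp[sx : sx + ckx, sy : sy + cky])


def add_noise(
    d: np.ndarray,
    psnr_db: float,
    seed: int = 0,
    per_channel_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, NoiseModel]:
    """Add channel-independent complex circular Gaussian k-space noise.

    The noise SD is set from the peak SNR (amplitude ratio, in dB):
    ``sigma = max|d| / 10**(psnr_db/20)``, so 60 dB gives ``max|d|/1000``.
    ``sigma`` is the SD of the complex sample (``E|n|^2 = sigma^2``, each
    real component ``sigma/sqrt(2)``), which makes the chi-square misfit
    statistic of a perfect reconstruction have mean exactly 1.

    Returns the noisy tensor and the per-receive-channel :class:`NoiseModel`
    used by the chi-square stopping rule.
    """
    d = np.asarray(d)
    nrx = d.shape[2]
    if per_channel_sd is not None:
        sd = np.asarray(per_channel_sd, dtype=float)
        if sd.shape != (nrx,):
            raise ValueError(f"per_channel_sd must have shape ({nrx},)")
    else:
        if np.isinf(psnr_db):
            return d.copy(), NoiseModel(sd=np.zeros(nrx))
        sigma = np.abs(d).max() / 10 ** (psnr_db / 20.0)
        sd = np.full(nrx, sigma)
    rng = np.random.default_rng(seed)
    noise = (rng.standard_normal(d.shape) + 1j * rng.standard_normal(d.shape)) / np.sqrt(2)
    noise *= sd[None, None, :, None]
    return d + noise, NoiseModel(sd=sd)


def make_dataset(
    nx: int = 64,
    ny: int = 64,
    nrx: int = 8,
    ntx: int = 8,
    crop: tuple[int, int] = (24, 24),
    psnr_db: float = 60.0,
    kind: str = "gaussian",
    seed: int = 0,
):
    """Convenience pipeline: phantom -> sensitivities -> k-space -> noise.

    Returns ``(noisy, clean, noise_model, phantom, tx, rx)`` with independent
    sub-seeds for each stochastic stage derived from ``seed``.
    """
    s = np.random.SeedSequence(seed).generate_state(4)
    ph = generate_phantom(nx, ny, seed=int(s[0] % 2**31))
    tx = generate_sensitivities(nx, ny, ntx, kind=kind, seed=int(s[1] % 2**31))
    rx = generate_sensitivities(nx, ny, nrx, kind=kind, seed=int(s[2] % 2**31))
    clean = simulate_kspace(ph, tx, rx, crop=crop)
    noisy, noise = add_noise(clean, psnr_db, seed=int(s[3] % 2**31))
    return noisy, clean, noise, ph, tx, rx
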