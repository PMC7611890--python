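"""Reconstruction fidelity metric and scan-time budget arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["rmse", "ScanBudget", "ScanBudgetResult", "scan_budget"]


def rmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Normalised RMSE ``||est - truth||_F / ||truth||_F``.

    Evaluated on the (cropped) k-space tensors; the natural fidelity metric
    for k-space completion.  A zero ground truth is rejected.
    """
    estimate = np.asarray(estimate)
    truth = np.asarray(truth)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimate.shape} vs {truth.shape}")
    denom = np.linalg.norm(truth)
    if denom == 0:
        raise ValueError("ground truth has zero norm")
    return float(np.linalg.norm(estimate - truth) / denom)


@dataclass
class ScanBudget:
    """Acquisition budget for a 3-D relative-mapping scan.

    ``matrix`` is the number of phase-encode lines per transmit encoding
    (ky * kz for a 3-D acquisition), ``ntx`` the transmit channel count,
    ``R`` the acceleration, ``tr_ms`` the repetition time and
    ``window_ms`` an optional cardiac acquisition window.
    """

    matrix: int
    ntx: int
    R: float = 1.0
    tr_ms: float = 3.5
    window_ms: float | None = 400.0

    def __post_init__(self):
        if self.matrix < 1 or self.ntx < 1 or self.R < 1 or self.tr_ms <= 0:
            raise ValueError("scan budget fields must be positive and R >= 1")


@dataclass
class ScanBudgetResult:
    lines: int
    seconds: float
    heartbeats: int | None


def scan_budget(b: ScanBudget) -> ScanBudgetResult:
    """Lines, duration and heartbeat count for an accelerated mapping scan.

    ``lines = ceil(matrix * ntx / R)``; ``seconds = lines * TR / 1000``
    (e.g. a 24 x 24 matrix with 8 transmit channels at TR = 3.5 ms needs
    4608 lines and 16.1 s unaccelerated); heartbeats is the duration
    divided by the cardiac window, rounded up.
    """
    lines = math.ceil(b.matrix * b.ntx / b.R)
    seconds = lines * b.tr_ms / 1000.0
    beats = math.ceil(seconds / (b.window_ms / 1000.0)) if b.window_ms else None
    return ScanBudgetResult(lines=lines, seconds=seconds, heartbeats=beats)
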