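"""Shared fixtures: small random tensors and the synthetic study dataset."""

import numpy as np
import pytest

import txlr


def random_kspace(shape, seed):
    rng = np.random.default_rng(seed)
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic 8Tx/8Rx 24x24 dataset at 60 dB peak SNR (one seed)."""
    noisy, clean, noise, ph, tx, rx = txlr.make_dataset(
        nx=64, ny=64, nrx=8, ntx=8, crop=(24, 24), psnr_db=60.0, seed=0
    )
    return {"noisy": noisy, "clean": clean, "noise": noise,
            "phantom": ph, "tx": tx, "rx": rx}


@pytest.fixture(scope="session")
def method_sweep():
    """RMSE of all three methods at R in {2,4,6,8}, three seeds.

    The desk-scale analogue of the synthetic-body acceleration sweep:
    8Tx/8Rx, 24x24 crop, 60 dB peak SNR, per-encoding Poisson-disc masks,
    default reconstruction parameters (kernel [5,5], ranks 50, 50
    iterations for TxLR / 100 for VC and PRIMO).  Shared by the acceptance
    tests; also returns the reconstructions for map-quality checks.
    """
    seeds = (0, 1, 2)
    out = {"rmse": {}, "recons": [], "cleans": {}}
    for seed in seeds:
        noisy, clean, noise, *_ = txlr.make_dataset(
            nx=64, ny=64, nrx=8, ntx=8, crop=(24, 24), psnr_db=60.0, seed=seed
        )
        out["cleans"][seed] = clean
        for method in ("txlr", "primo", "vc"):
            for R in (2, 4, 6, 8):
                mask = txlr.poisson_disc_mask(24, 24, 8, R, seed=1000 + seed)
                z, log = txlr.run_admm(
                    noisy * mask[:, :, None, :], mask,
                    txlr.ReconConfig(method=method), truth=clean,
                )
                err = log[-1]["rmse"]
                out["rmse"].setdefault((method, R), []).append(err)
                out["recons"].append(
                    {"method": method, "R": R, "seed": seed, "z": z, "rmse": err}
                )
    return out
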