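import numpy as np
import pytest

from mtdyn.simulate import (SimImageConfig, apply_poisson_noise,
                            random_seed_filaments, render_filaments)

PSF_SIGMA = SimImageConfig().psf_sigma_px[0]   # FWHM 199 nm at 156 nm/px


@pytest.fixture(scope="session")
def small_config():
    return SimImageConfig(width_px=160, height_px=160, rng_seed=11)


@pytest.fixture(scope="session")
def seed_scene(small_config):
    """Five straight seeds, clean + SNR-5 noisy rendering."""
    fils = random_seed_filaments(small_config, 5,
                                 rng=np.random.default_rng(21))
    clean = render_filaments(small_config, fils)
    noisy = apply_poisson_noise(clean, 5.0, 22,
                                background=small_config.background)
    return small_config, fils, clean, noisy


def endpoint_errors(filaments, detected):
    """Match ground-truth filaments to nearest detection.

    Returns (euclidean errors, signed along-axis errors with + = inward)
    for the two endpoints of every matched filament; filaments whose best
    match is further than 10 px (summed over both endpoints) are skipped
    as detection failures.
    """
    errs, signed = [], []
    for f in filaments:
        g = np.array(f.true_endpoints)
        best, best_sum = None, np.inf
        for det in detected:
            e1 = np.linalg.norm(det.endpoints - g, axis=1).sum()
            e2 = np.linalg.norm(det.endpoints - g[::-1], axis=1).sum()
            if min(e1, e2) < best_sum:
                best_sum, best = min(e1, e2), (det, e1 < e2)
        if best is None or best_sum > 10.0:
            continue
        det, forward = best
        gm = g if forward else g[::-1]
        for k in range(2):
            err = det.endpoints[k] - gm[k]
            axis = (gm[1] - gm[0]) if k == 0 else (gm[0] - gm[1])
            axis = axis / np.linalg.norm(axis)
            errs.append(float(np.linalg.norm(err)))
            signed.append(float(err @ axis))
    return np.array(errs), np.array(signed)
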