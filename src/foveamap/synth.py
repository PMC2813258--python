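"""Synthetic sparse retinotopy samples for parameter-recovery studies.

Emulates the kind of data produced by retinotopic mapping experiments:
per visual area, a sparse set of visual-field positions together with
the cortical flat-map coordinates at which they are represented,
corrupted by isotropic Gaussian position noise.  Eccentricities are
drawn log-uniformly (matching the roughly log-uniform coverage of
typical eccentricity designs) and polar angles uniformly over each
area's quadrant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ModelParams
from .wedge import AreaLabel, VisualAreaMap

__all__ = ["generate_synthetic_retinotopy"]

#: eccentricity coverage of the synthetic experiments, degrees
DEFAULT_ECC_RANGE = (0.2, 12.0)


def generate_synthetic_retinotopy(
    true_params: ModelParams,
    n_per_area: int = 100,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    banded: bool = True,
    ecc_range: tuple[float, float] = DEFAULT_ECC_RANGE,
) -> pd.DataFrame:
    """Draw noisy retinotopy samples from a ground-truth model.

    Returns a tidy frame with columns ``ecc_deg, polar_rad, x_mm, y_mm,
    area`` plus the noiseless positions ``x0_mm, y0_mm``; the noise level
    used is recorded in ``DataFrame.attrs["noise_sd_mm"]``.
    """
    if n_per_area < 1:
        raise ValueError("n_per_area must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    model = VisualAreaMap(true_params, banded=banded)
    lo, hi = np.log(ecc_range[0]), np.log(ecc_range[1])

    frames = []
    for area in AreaLabel:
        E = np.exp(rng.uniform(lo, hi, size=n_per_area))
        if area == AreaLabel.V1:
            th = rng.uniform(-np.pi / 2, np.pi / 2, size=n_per_area)
        elif area in (AreaLabel.V2v, AreaLabel.V3v):
            th = rng.uniform(0.0, np.pi / 2, size=n_per_area)
        else:
            th = rng.uniform(-np.pi / 2, 0.0, size=n_per_area)
        w = model.project(E, th, area)
        noise = rng.normal(0.0, noise_sd, size=(n_per_area, 2))
        frames.append(pd.DataFrame({
            "ecc_deg": E,
            "polar_rad": th,
            "x_mm": np.real(w) + noise[:, 0],
            "y_mm": np.imag(w) + noise[:, 1],
            "x0_mm": np.real(w),
            "y0_mm": np.imag(w),
            "area": area.value,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.attrs["noise_sd_mm"] = float(noise_sd)
    df.attrs["banded"] = bool(banded)
    df.attrs["variant"] = true_params.variant
    return df
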