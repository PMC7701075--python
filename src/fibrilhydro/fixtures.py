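"""Seeded synthetic data emulating the study's inputs.

No public dataset accompanies the measurements, so every input the
analysis modules consume is generated here to the statistics the study
states: lognormal fibril length samples with a mean of 395 nm truncated
to 80--810 nm, normal fibril heights of 4.0 +- 1.0 nm, Weibull-shaped
sedimentation-coefficient densities, the three-species sweep
configuration (4/50/100 S), and power-law comminution series over the
11--24 krpm x 5--90 s stressing grid.  All generators take a mandatory
seed and are deterministic given it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import lognorm

from .auc_sweep_simulator import SpeciesSpec, SweepConfig
from .comminution_scaling import ComminutionSeries
from .distribution_engine import WeightedDistribution

__all__ = [
    "truncated_lognormal_mu",
    "generate_afm_lengths",
    "generate_afm_table",
    "reference_sweep",
    "generate_weibull_s_distribution",
    "generate_comminution_series",
    "STRESSING_GRID",
]

#: Stressing grid of the rotor-stator experiments: rpm x seconds
STRESSING_GRID = tuple(
    (rpm, secs)
    for rpm in (11000, 13000, 16000, 19000, 22000, 24000)
    for secs in (5, 30, 60, 90)
)

#: Default lognormal shape (sigma of ln length) of AFM length samples;
#: chosen so that ~2000-sample extremes fall near the stated 80/810 nm
#: bounds around a 395 nm mean.
DEFAULT_LENGTH_SHAPE = 0.35


def truncated_lognormal_mu(
    target_mean: float, sigma: float, lo: float, hi: float
) -> float:
    """ln-scale location so the [lo, hi]-truncated lognormal has the
    target mean.  Solved deterministically by bracketed root search."""
    if lo >= hi:
        raise ValueError(f"infeasible truncation: lo = {lo} >= hi = {hi}")
    if not (lo < target_mean < hi):
        raise ValueError("target mean must lie inside the truncation bounds")

    def trunc_mean(mu: float) -> float:
        dist = lognorm(s=sigma, scale=np.exp(mu))
        # E[X; lo<X<hi] / P(lo<X<hi) via the lognormal partial expectation
        a, b = dist.cdf(lo), dist.cdf(hi)
        full = np.exp(mu + sigma**2 / 2.0)
        z = lambda x: (np.log(x) - mu) / sigma
        from scipy.special import ndtr

        partial = full * (ndtr(z(hi) - sigma) - ndtr(z(lo) - sigma))
        return partial / (b - a)

    return brentq(
        lambda mu: trunc_mean(mu) - target_mean,
        np.log(lo), np.log(hi), xtol=1e-12,
    )


def generate_afm_lengths(
    n: int = 2000,
    mean_nm: float = 395.0,
    min_nm: float = 80.0,
    max_nm: float = 810.0,
    shape: float = DEFAULT_LENGTH_SHAPE,
    seed: int = 0,
) -> np.ndarray:
    """Lognormal fibril length sample [nm], truncated to [min, max].

    Defaults reproduce the reference AFM sample: 2000 records, mean
    395 nm, extremes at 80 and 810 nm.  Rejection sampling from the
    mean-matched lognormal; deterministic given the seed.
    """
    if n < 10:
        raise ValueError("need at least 10 records for a meaningful sample")
    mu = truncated_lognormal_mu(mean_nm, shape, min_nm, max_nm)
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mu, shape, size=2 * n)
        draw = draw[(draw >= min_nm) & (draw <= max_nm)]
        out = np.concatenate([out, draw])
    return out[:n]


def generate_afm_table(
    path=None,
    n: int = 2000,
    mean_nm: float = 395.0,
    min_nm: float = 80.0,
    max_nm: float = 810.0,
    shape: float = DEFAULT_LENGTH_SHAPE,
    height_mean_nm: Optional[float] = 4.0,
    height_sd_nm: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """AFM table (length_nm[, height_nm]); optionally written as CSV.

    Heights are normal (truncated at 0.5 nm); pass
    ``height_mean_nm=None`` to omit the column.
    """
    lengths = generate_afm_lengths(n, mean_nm, min_nm, max_nm, shape, seed)
    frame = pd.DataFrame({"length_nm": lengths})
    if height_mean_nm is not None:
        rng = np.random.default_rng(seed + 1)
        h = rng.normal(height_mean_nm, height_sd_nm, size=n)
        h = np.clip(h, 0.5, None)
        frame["height_nm"] = h
    if path is not None:
        from .io import _meta_header

        with open(path, "w") as fh:
            fh.write(_meta_header(seed=seed, generator="afm_lengths"))
            frame.to_csv(fh, index=False)
    return frame


def reference_sweep(seed: int = 0, n_particles: int = 100_000) -> tuple:
    """The three-species gravitational-sweep configuration.

    Non-aggregated material at 4 S (f/f0 = 1.26, monomer density
    1331.6 kg m^-3) plus fibril-like species at 50 S and 100 S
    (f/f0 = 1.5, density 2% above the monomer), equal abundances;
    30,000 rpm for 7200 s, meniscus 5.9 cm, bottom 7.2 cm, detector
    6.9 cm, 10 S analysis cutoff.
    """
    config = SweepConfig(
        rotor_rpm=30000.0,
        meniscus_m=0.059,
        bottom_m=0.072,
        detector_m=0.069,
        duration_s=7200.0,
        dt_s=0.5,
        n_particles=n_particles,
        seed=seed,
        cutoff_svedberg=10.0,
    )
    species = [
        SpeciesSpec(s_svedberg=4.0, frictional_ratio=1.26, density=1331.6, abundance=1 / 3),
        SpeciesSpec(s_svedberg=50.0, frictional_ratio=1.5, density=1331.6 * 1.02, abundance=1 / 3),
        SpeciesSpec(s_svedberg=100.0, frictional_ratio=1.5, density=1331.6 * 1.02, abundance=1 / 3),
    ]
    return config, species


def generate_weibull_s_distribution(
    shape: float = 2.0,
    scale_svedberg: float = 30.0,
    loc_svedberg: float = 5.0,
    n_grid: int = 200,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> WeightedDistribution:
    """Weibull-shaped extinction-weighted s-density on a linear grid.

    Defaults put the mode near 26 S, within the 25--42 S band the
    stressed-fibril measurements span.  ``noise_sd_frac`` adds seeded
    Gaussian noise as a fraction of the peak density.
    """
    grid = np.linspace(loc_svedberg + 1e-3, loc_svedberg + 4 * scale_svedberg, n_grid)
    z = (grid - loc_svedberg) / scale_svedberg
    dens = (shape / scale_svedberg) * z ** (shape - 1) * np.exp(-(z**shape))
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        dens = dens + rng.normal(0.0, noise_sd_frac * dens.max(), size=dens.shape)
        dens = np.clip(dens, 0.0, None)
    dist = WeightedDistribution(
        "sedimentation_coefficient", grid, dens, "extinction",
        metadata={"generator": "weibull_s", "seed": seed,
                  "true_shape": shape, "true_scale": scale_svedberg,
                  "true_loc": loc_svedberg},
    )
    return dist.normalized()


def generate_comminution_series(
    b: float = 0.2,
    length_at_n1_nm: float = 5.5e4,
    noise_sd_frac: float = 0.05,
    conditions: Sequence[tuple] = STRESSING_GRID,
    statistic: str = "modal",
    source: str = "AFM",
    seed: int = 0,
) -> ComminutionSeries:
    """Power-law comminution series l = a n^(-3b) with multiplicative noise.

    The defaults span the observed 100--800 nm modal-length range across
    the full stressing grid (~900 to ~36,000 rotations), which pins the
    effective exponent near b = 0.2 with a prefactor of 5.5e4 nm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rpm, secs in conditions:
        n = rpm / 60.0 * secs
        length = length_at_n1_nm * n ** (-3.0 * b)
        if noise_sd_frac > 0:
            length *= np.exp(rng.normal(0.0, noise_sd_frac))
        rows.append((float(rpm), float(secs), float(length), statistic, source))
    return ComminutionSeries.from_records(rows)
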