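"""Relaxation-decay fitting and NERRD profile assembly.

R1 and R1rho rates come from two-parameter monoexponential fits of peak
intensity versus relaxation (or spin-lock) delay, with Monte Carlo
uncertainties from resampling the intensities at the spectral noise level.
A NERRD (near-rotary-resonance relaxation dispersion) profile collects
R1rho rates measured at increasing spin-lock rf field strength; a profile
that rises as the rf field approaches the MAS frequency reports on
microsecond-timescale motion.  The paper-standard water-shift thermometer
T = 455 - 90 * delta_H2O is provided as a utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "RelaxationDecay",
    "RateEstimate",
    "NerrdProfile",
    "fit_monoexponential",
    "assemble_nerrd",
    "temperature_from_water_shift",
    "MonoexponentialFitter",
    "R1_DELAYS",
]

#: longitudinal-relaxation delay grid (s) used as the synthetic template
R1_DELAYS = (0.05, 0.2, 0.4, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0, 2.5)


@dataclass
class RelaxationDecay:
    """Peak-intensity decay versus delay, tagged by spin-lock rf field."""

    delays: np.ndarray
    intensities: np.ndarray
    intensity_sigma: float = 0.0
    spin_lock_rf: float = 0.0  # Hz; 0 denotes an R1 measurement
    mas_frequency: float = 0.0

    def __post_init__(self):
        self.delays = np.asarray(self.delays, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must match in length")
        if np.any(self.delays < 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be >= 0 and strictly increasing")


@dataclass
class RateEstimate:
    """Fitted relaxation rate (s^-1) with its MC uncertainty."""

    rate: float
    rate_sd: float
    amplitude: float
    spin_lock_rf: float = 0.0


@dataclass
class NerrdProfile:
    """R1rho versus spin-lock field, with a flatness classification."""

    points: list
    mas_frequency: float
    nerrd_delta: float
    nerrd_delta_sd: float
    is_nonflat: bool


def _monoexp(t, amp, rate):
    return amp * np.exp(-rate * t)


def _fit_once(delays, intensities):
    scale = np.max(np.abs(intensities))
    if scale == 0:
        return 0.0, 0.0
    span = delays[-1] - delays[0]
    # log-linear start values keep curve_fit off pathological plateaus
    r0 = 1.0 / span
    pos = intensities > 0
    if pos.sum() >= 2:
        slope = np.polyfit(delays[pos], np.log(intensities[pos]), 1)[0]
        if slope < 0:
            r0 = -slope
    try:
        popt, _ = curve_fit(_monoexp, delays, intensities,
                            p0=(intensities[0], r0), maxfev=5000)
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return float(intensities[0]), 0.0


def fit_monoexponential(decay: RelaxationDecay, seed: int | None = None,
                        n_mc: int = 1000) -> RateEstimate:
    """Two-parameter monoexponential fit I(t) = I0 exp(-R t).

    The rate is fitted without a positivity constraint (so residual
    diagnostics stay honest) and floored at zero afterwards; the rate SD is
    the standard deviation over ``n_mc`` seeded refits with normal noise of
    SD ``intensity_sigma`` added to the intensities.  Non-decaying or
    all-zero data produce a warning, rate 0 and an inflated SD.
    """
    if decay.delays.size < 3:
        raise ValueError("need at least 3 points for a two-parameter fit")
    amp, rate = _fit_once(decay.delays, decay.intensities)
    if rate < 0 or np.all(decay.intensities == 0):
        warnings.warn("non-decaying or empty intensity data; reporting "
                      "rate 0 with an inflated uncertainty", stacklevel=2)
        span = decay.delays[-1] - decay.delays[0]
        return RateEstimate(0.0, 10.0 / span, amp, decay.spin_lock_rf)

    sd = 0.0
    if decay.intensity_sigma > 0 and n_mc >= 2:
        rng = np.random.default_rng(seed)
        rates = np.empty(n_mc)
        for i in range(n_mc):
            noisy = decay.intensities + rng.normal(
                0.0, decay.intensity_sigma, decay.intensities.size)
            rates[i] = max(_fit_once(decay.delays, noisy)[1], 0.0)
        sd = float(np.std(rates))
    return RateEstimate(max(rate, 0.0), sd, amp, decay.spin_lock_rf)


def assemble_nerrd(rates: list[RateEstimate], mas_frequency: float,
                   flat_threshold_sd: float = 3.0) -> NerrdProfile:
    """Order R1rho rates by spin-lock field and classify the dispersion.

    ``nerrd_delta`` is the rate at the highest field minus the rate at the
    lowest; the profile is flagged non-flat when the delta exceeds
    ``flat_threshold_sd`` times its propagated SD.  Spin-lock fields at or
    above the MAS frequency are rejected (n = 1 rotary-resonance condition).
    """
    if len(rates) < 2:
        raise ValueError("need rates at >= 2 spin-lock fields")
    for r in rates:
        if r.spin_lock_rf >= mas_frequency:
            raise ValueError(
                f"spin-lock field {r.spin_lock_rf} Hz is at or above the "
                f"MAS frequency {mas_frequency} Hz (rotary resonance)")
    pts = sorted(rates, key=lambda r: r.spin_lock_rf)
    if len({r.spin_lock_rf for r in pts}) < 2:
        raise ValueError("need >= 2 distinct spin-lock fields")
    delta = pts[-1].rate - pts[0].rate
    delta_sd = float(np.hypot(pts[-1].rate_sd, pts[0].rate_sd))
    nonflat = bool(delta > flat_threshold_sd * delta_sd) if delta_sd > 0 \
        else bool(delta > 0)
    return NerrdProfile(pts, mas_frequency, float(delta), delta_sd, nonflat)


def temperature_from_water_shift(water_shift: float) -> float:
    """Sample temperature (deg C) from the bulk-water shift (ppm)."""
    return 455.0 - 90.0 * water_shift


class MonoexponentialFitter(BaseEstimator):
    """Monoexponential decay fit as an sklearn-style estimator.

    After :meth:`fit` exposes ``rate_``, ``amplitude_`` and ``rate_sd_``.
    """

    def __init__(self, intensity_sigma: float = 0.0, n_mc: int = 1000,
                 seed: int | None = None, spin_lock_rf: float = 0.0):
        self.intensity_sigma = intensity_sigma
        self.n_mc = n_mc
        self.seed = seed
        self.spin_lock_rf = spin_lock_rf

    def fit(self, X, y):
        """Fit intensities ``y`` observed at delays ``X`` (s)."""
        decay = RelaxationDecay(np.asarray(X, float).reshape(-1),
                                np.asarray(y, float).reshape(-1),
                                self.intensity_sigma, self.spin_lock_rf)
        est = fit_monoexponential(decay, self.seed, self.n_mc)
        self.result_ = est
        self.rate_ = est.rate
        self.rate_sd_ = est.rate_sd
        self.amplitude_ = est.amplitude
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator first")
        return self.amplitude_ * np.exp(-self.rate_ *
                                        np.asarray(X, float).reshape(-1))
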