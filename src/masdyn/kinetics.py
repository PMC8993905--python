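"""Plate-reader enzyme kinetics: initial rates and Michaelis-Menten fits.

Absorbance traces of a chromogenic (p-nitroanilide) substrate are blank
subtracted, converted to product concentration with Beer-Lambert
(epsilon = 8800 M^-1 cm^-1, path 0.375 cm for the default plate geometry),
and the initial rate is extracted by a linear fit over the early part of
the trace.  Initial rates at a series of substrate concentrations are
fitted jointly (duplicates included as separate points) to
v(S) = Vmax S / (KM + S); kcat = Vmax / [E]_sites.  Parameter
uncertainties come from 1000 Monte Carlo refits with normal noise at each
point's slope standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "KineticTrace",
    "AbsorbanceModel",
    "MichaelisMentenFit",
    "absorbance_to_concentration",
    "initial_rate",
    "fit_michaelis_menten",
    "site_concentration",
    "MichaelisMentenFitter",
]


@dataclass
class KineticTrace:
    """One well's absorbance time trace."""

    times: np.ndarray
    absorbance: np.ndarray
    substrate_conc: float = 0.0   # M
    is_blank: bool = False
    enzyme_conc: float = 0.0      # g/L

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must match in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.substrate_conc < 0:
            raise ValueError("substrate_conc must be >= 0")


@dataclass(frozen=True)
class AbsorbanceModel:
    """Beer-Lambert conversion constants for the product chromophore."""

    epsilon: float = 8800.0     # M^-1 cm^-1
    path_length: float = 0.375  # cm

    def __post_init__(self):
        if self.epsilon <= 0 or self.path_length <= 0:
            raise ValueError("epsilon and path_length must be > 0")


@dataclass
class MichaelisMentenFit:
    """Joint Michaelis-Menten fit with Monte Carlo uncertainties."""

    km: float        # M
    kcat: float      # s^-1
    km_sd: float
    kcat_sd: float
    vmax: float      # M s^-1
    kcat_over_km: float  # M^-1 s^-1


def absorbance_to_concentration(a, model: AbsorbanceModel = AbsorbanceModel()):
    """Product concentration (M) from absorbance: c = A / (epsilon * l)."""
    return np.asarray(a, float) / (model.epsilon * model.path_length)


def site_concentration(protein_conc_g_per_l: float = 5e-3,
                       subunit_mass_da: float = 39000.0,
                       sites_per_subunit: int = 1) -> float:
    """Active-site molar concentration from a mass concentration.

    Defaults: 5 ng/uL (= 5e-3 g/L) final protein, 39 kDa per subunit, one
    site per subunit.
    """
    return protein_conc_g_per_l / subunit_mass_da * sites_per_subunit


def initial_rate(trace: KineticTrace, blank: KineticTrace | None = None,
                 model: AbsorbanceModel = AbsorbanceModel(),
                 window_fraction: float = 0.1):
    """Initial product-formation rate (M/s) and its standard error.

    The blank trace is subtracted (interpolated to the trace's times if
    sampled differently), absorbance is converted to concentration, and a
    straight line is fitted over the initial window: the first
    ``window_fraction`` of the points or up to 10% substrate depletion,
    whichever is shorter (never fewer than 3 points).
    """
    a = trace.absorbance
    if blank is not None:
        if blank.times.shape == trace.times.shape and \
                np.allclose(blank.times, trace.times):
            a = a - blank.absorbance
        else:
            a = a - np.interp(trace.times, blank.times, blank.absorbance)
    conc = absorbance_to_concentration(a, model)

    n = conc.size
    n_window = max(int(np.ceil(window_fraction * n)), 3)
    if trace.substrate_conc > 0:
        depleted = np.nonzero(conc - conc[0] >= 0.1 * trace.substrate_conc)[0]
        if depleted.size:
            n_window = min(n_window, max(int(depleted[0]) + 1, 3))
    if n_window > n:
        raise ValueError("fewer than 3 points in the initial-rate window")

    t, c = trace.times[:n_window], conc[:n_window]
    res = lmfit.models.LinearModel().fit(c, x=t)
    slope = float(res.params["slope"].value)
    stderr = res.params["slope"].stderr
    return slope, float(stderr) if stderr is not None else 0.0


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def _fit_mm_once(s, v, weights=None):
    vmax0 = float(np.max(v)) if np.max(v) > 0 else 1.0
    half = np.abs(v - vmax0 / 2)
    km0 = float(s[np.argmin(half)]) if np.any(s > 0) else 1.0
    km0 = max(km0, np.min(s[s > 0]) if np.any(s > 0) else 1e-6)
    sigma = None if weights is None else weights
    popt, _ = curve_fit(_mm, s, v, p0=(vmax0, km0), sigma=sigma,
                        maxfev=10000)
    return float(popt[0]), float(popt[1])


def fit_michaelis_menten(rates, enzyme_site_conc: float, n_mc: int = 1000,
                         seed: int | None = None, *,
                         weighted: bool = False) -> MichaelisMentenFit:
    """Joint Michaelis-Menten fit of (substrate_conc, rate, rate_se) points.

    All points, duplicates included, enter one least-squares fit of
    v(S) = Vmax S / (KM + S) (unweighted by default; ``weighted=True``
    weights by the slope standard errors).  kcat = Vmax / enzyme_site_conc.
    SDs are standard deviations over ``n_mc`` refits of data resampled with
    normal noise of SD equal to each point's rate_se.  Poorly identified
    fits (KM outside the sampled substrate range by more than a decade)
    trigger a warning.
    """
    rates = [(float(s), float(v), float(se)) for s, v, se in rates]
    s = np.array([r[0] for r in rates])
    v = np.array([r[1] for r in rates])
    se = np.array([r[2] for r in rates])
    if len(set(s)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if enzyme_site_conc <= 0:
        raise ValueError("enzyme_site_conc must be > 0")

    w = se if (weighted and np.all(se > 0)) else None
    vmax, km = _fit_mm_once(s, v, w)
    if not (np.min(s) / 10 <= km <= np.max(s) * 10):
        warnings.warn(
            f"KM = {km:.3g} M is far outside the sampled substrate range "
            "[{:.3g}, {:.3g}] M; the fit is poorly identified and the "
            "Monte Carlo SDs will be inflated".format(np.min(s), np.max(s)),
            stacklevel=2)

    km_sd = kcat_sd = 0.0
    if n_mc >= 2 and np.any(se > 0):
        rng = np.random.default_rng(seed)
        kms, vmaxs = [], []
        for _ in range(n_mc):
            noisy = v + rng.normal(0.0, se)
            try:
                vm, k = _fit_mm_once(s, noisy, w)
            except RuntimeError:
                continue
            vmaxs.append(vm)
            kms.append(k)
        if len(kms) >= 2:
            km_sd = float(np.std(kms))
            kcat_sd = float(np.std(vmaxs) / enzyme_site_conc)

    kcat = vmax / enzyme_site_conc
    return MichaelisMentenFit(km, kcat, km_sd, kcat_sd, vmax, kcat / km)


class MichaelisMentenFitter(BaseEstimator):
    """Michaelis-Menten regression as an sklearn-style estimator.

    ``fit(X, y)`` takes substrate concentrations (M) and initial rates
    (M/s); per-point rate standard errors go in ``rate_se``.  After
    fitting exposes ``km_``, ``kcat_``, ``vmax_``, ``km_sd_``, ``kcat_sd_``.
    """

    def __init__(self, enzyme_site_conc: float = 1.0, n_mc: int = 1000,
                 seed: int | None = None, weighted: bool = False):
        self.enzyme_site_conc = enzyme_site_conc
        self.n_mc = n_mc
        self.seed = seed
        self.weighted = weighted

    def fit(self, X, y, rate_se=None):
        s = np.asarray(X, float).reshape(-1)
        v = np.asarray(y, float).reshape(-1)
        se = (np.zeros_like(v) if rate_se is None
              else np.asarray(rate_se, float).reshape(-1))
        res = fit_michaelis_menten(list(zip(s, v, se)), self.enzyme_site_conc,
                                   self.n_mc, self.seed,
                                   weighted=self.weighted)
        self.result_ = res
        self.km_ = res.km
        self.kcat_ = res.kcat
        self.vmax_ = res.vmax
        self.km_sd_ = res.km_sd
        self.kcat_sd_ = res.kcat_sd
        self.kcat_over_km_ = res.kcat_over_km
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator first")
        s = np.asarray(X, float).reshape(-1)
        return self.vmax_ * s / (self.km_ + s)
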