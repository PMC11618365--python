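"""Psychometric fits, criterion thresholds, cue weights, and SRT analysis.

Accuracy as a function of a stimulus variable is modeled as a cumulative
Normal, Phi((x - mu)/sigma), fitted by maximum likelihood under a binomial
observation model. Thresholds are read off at a stated criterion
(70.7% for two-interval lateralization tasks, 75% for two-alternative
discrimination, half-maximal performance for speech reception thresholds),
either from the fit or by linear interpolation of the raw psychometric
function. Thresholds that the psychometric function never reaches are
reported as unmeasurable rather than extrapolated.

The fitting surface follows the statsmodels convention: a
:class:`PsychometricModel` is built from data and ``fit()`` returns a
:class:`PsychometricFit` carrying estimates, diagnostics and a
``summary()`` table. The module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricModel",
    "PsychometricFit",
    "ThresholdResult",
    "fit_psychometric",
    "threshold",
    "lateralization_judgments",
    "perceptual_weight",
    "woodworth_itd",
    "sine_ild",
    "srt",
    "tfs_benefit",
]


@dataclass
class ThresholdResult:
    """A criterion-level threshold.

    ``measurable=False`` marks psychometric functions that never reach the
    criterion (the "unmeasurably high" threshold case); ``threshold`` is NaN
    then.
    """

    criterion: float
    threshold: float
    method: str
    measurable: bool = True

    def __repr__(self) -> str:  # compact, table-friendly
        val = f"{self.threshold:.6g}" if self.measurable else "unmeasurable"
        return f"ThresholdResult({val} @ {self.criterion:.3g}, {self.method})"


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Normal fit of a psychometric function.

    With a chance floor gamma (0 for yes/no-style proportions, 0.5 for
    2AFC accuracy), the response model is gamma + (1-gamma)*Phi((x-mu)/sigma).
    """

    mu: float
    sigma: float
    loglike: float
    n_obs: int
    converged: bool
    x: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    chance: float = 0.0

    def predict(self, x) -> np.ndarray:
        """Predicted proportion at stimulus value(s) ``x``."""
        base = norm.cdf((np.asarray(x, float) - self.mu) / self.sigma)
        return self.chance + (1.0 - self.chance) * base

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of (mu, sigma) from the observed information.

        Finite-difference Hessian of the negative log-likelihood in
        (mu, log sigma), inverted and transformed back to the sigma scale.
        """
        model = PsychometricModel(self.x, self.k, self.n, chance=self.chance)
        th = np.array([self.mu, np.log(self.sigma)])

        def nll(t):
            return -model.loglike(t[0], float(np.exp(t[1])))

        h = np.array([1e-4 * max(abs(self.mu), self.sigma, 1e-6), 1e-4])
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = (
                    nll(th + ei + ej) - nll(th + ei - ej)
                    - nll(th - ei + ej) + nll(th - ei - ej)
                ) / (4 * h[i] * h[j])
        cov_t = np.linalg.inv(H)  # covariance in (mu, log sigma)
        jac = np.array([[1.0, 0.0], [0.0, self.sigma]])
        return jac @ cov_t @ jac.T

    def threshold_se(self, criterion: float) -> float:
        """Delta-method standard error of the criterion threshold."""
        z = norm.ppf((criterion - self.chance) / (1.0 - self.chance))
        cov = self.cov_params()
        g = np.array([1.0, z])
        return float(np.sqrt(g @ cov @ g))

    def threshold(self, criterion: float) -> ThresholdResult:
        """Stimulus value where the fit crosses ``criterion``: mu + sigma*Phi^-1(c)."""
        return threshold(self, criterion, method="fit")

    def summary(self) -> str:
        lines = [
            "Cumulative-Normal psychometric fit (binomial ML)",
            "=" * 48,
            f"{'location mu':<20}{self.mu: .6g}",
            f"{'scale sigma':<20}{self.sigma: .6g}",
            f"{'log-likelihood':<20}{self.loglike: .6g}",
            f"{'levels / trials':<20}{self.x.size} / {self.n_obs}",
            f"{'converged':<20}{self.converged}",
        ]
        return "\n".join(lines)


class PsychometricModel:
    """Binomial observation model with a cumulative-Normal response curve.

    Parameters
    ----------
    x : array
        Stimulus values (>= 3 distinct levels).
    k : array
        Successes per level.
    n : array
        Trials per level (each >= 1).
    chance : float
        Lower asymptote (0.5 for 2AFC accuracy data, default 0).
    """

    def __init__(self, x, k, n, chance: float = 0.0):
        self.x = np.asarray(x, float)
        self.k = np.asarray(k, float)
        self.n = np.asarray(n, float)
        if not (0 <= chance < 1):
            raise ValueError("chance must lie in [0, 1)")
        self.chance = chance
        if not (self.x.shape == self.k.shape == self.n.shape):
            raise ValueError("x, k, n must have matching shapes")
        if np.unique(self.x).size < 3:
            raise ValueError("need at least 3 distinct stimulus values")
        if np.any(self.n < 1) or np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("require 0 <= k <= n and n >= 1")

    def loglike(self, mu: float, sigma: float) -> float:
        p = self.chance + (1 - self.chance) * norm.cdf((self.x - mu) / sigma)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log(1 - p)))

    def fit(self) -> PsychometricFit:
        prop = self.k / self.n
        if np.all(prop == prop[0]) or np.all(prop <= self.chance) or np.all(prop >= 1):
            raise ValueError("degenerate data: psychometric function is flat")
        # probit-regression start values from a linearizing transform
        inner = (np.clip(prop, self.chance + 1e-3, 1 - 1e-3) - self.chance) / (1 - self.chance)
        z = norm.ppf(np.clip(inner, 0.01, 0.99))
        A = np.vstack([np.ones_like(self.x), self.x]).T
        b0, b1 = np.linalg.lstsq(A, z, rcond=None)[0]
        if b1 <= 0:
            b1 = 1.0 / max(np.ptp(self.x), 1e-6)
            b0 = -b1 * np.mean(self.x)
        mu0, sigma0 = -b0 / b1, 1.0 / b1

        def nll(theta):
            return -self.loglike(theta[0], np.exp(theta[1]))

        res = minimize(nll, x0=[mu0, np.log(max(sigma0, 1e-9))], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000})
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        # perfect separation: every level at the floor or the ceiling, so the
        # scale is unidentified (likelihood increases as sigma -> 0)
        at_floor = prop <= self.chance
        at_ceil = prop >= 1.0
        separated = bool(np.all(at_floor | at_ceil))
        converged = bool(res.success) and not separated
        # perfect step data: the scale collapses but the location is meaningful
        return PsychometricFit(mu, sigma, -res.fun, int(self.n.sum()), converged,
                               self.x, self.k, self.n, chance=self.chance)


def fit_psychometric(x, k, n, chance: float = 0.0) -> PsychometricFit:
    """Fit a cumulative-Normal psychometric function (binomial ML)."""
    return PsychometricModel(x, k, n, chance=chance).fit()


def threshold(fit_or_data, criterion: float, method: str = "fit", x=None) -> ThresholdResult:
    """Stimulus value at which accuracy reaches ``criterion``.

    ``method='fit'`` expects a :class:`PsychometricFit` and returns
    mu + sigma * Phi^-1(criterion). ``method='interpolation'`` expects raw
    accuracies (with the stimulus grid in ``x``) and linearly interpolates
    the first crossing of the criterion. A function that never reaches the
    criterion yields ``measurable=False``.
    """
    if not (0 < criterion < 1):
        raise ValueError("criterion must lie in (0, 1)")
    if method == "fit":
        fit: PsychometricFit = fit_or_data
        if criterion <= fit.chance:
            raise ValueError("criterion at or below the chance floor")
        inner = (criterion - fit.chance) / (1.0 - fit.chance)
        thr = fit.mu + fit.sigma * norm.ppf(inner)
        hi = fit.predict(fit.x.max())
        if not (hi >= criterion or np.isclose(hi, criterion)):
            return ThresholdResult(criterion, np.nan, "fit", measurable=False)
        return ThresholdResult(criterion, float(thr), "fit")
    if method == "interpolation":
        if x is None:
            raise ValueError("interpolation needs the stimulus grid in x")
        acc = np.asarray(fit_or_data, float)
        xs = np.asarray(x, float)
        if xs.shape != acc.shape:
            raise ValueError("interpolation needs matching x grid")
        above = acc >= criterion
        if not above.any():
            return ThresholdResult(criterion, np.nan, "interpolation", measurable=False)
        i = int(np.argmax(above))
        if i == 0:
            return ThresholdResult(criterion, float(xs[0]), "interpolation")
        x0, x1, y0, y1 = xs[i - 1], xs[i], acc[i - 1], acc[i]
        thr = x0 + (criterion - y0) * (x1 - x0) / (y1 - y0)
        return ThresholdResult(criterion, float(thr), "interpolation")
    raise ValueError(f"unknown method {method!r}")


def lateralization_judgments(est1, est2, seed: int | None = None) -> float:
    """Proportion of trials judged "second stimulus further right".

    A trial counts as rightward when the signed estimate for the second
    stimulus exceeds the first; exact ties are broken at random (seeded).
    """
    a = np.asarray(est1, float)
    b = np.asarray(est2, float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("paired, non-empty estimates required")
    right = b > a
    ties = b == a
    if ties.any():
        rng = np.random.default_rng(seed)
        right = right | (ties & (rng.random(a.shape) < 0.5))
    return float(np.mean(right))


def _reflect_to_front(az_deg):
    """Reflect rear-hemifield azimuths across the coronal plane."""
    az = np.mod(np.asarray(az_deg, float) + 180.0, 360.0) - 180.0
    rear = np.abs(az) > 90.0
    az = np.where(rear, np.sign(az) * (180.0 - np.abs(az)), az)
    return az


def woodworth_itd(az_deg, head_radius: float = 0.0875, c: float = 343.0):
    """Spherical-head (Woodworth) azimuth -> ITD map, in µs.

    A synthetic stand-in for HRTF-derived mappings: itd = r/c * (sin a + a)
    with a the azimuth in radians. Users with measured tables should supply
    their own map.
    """
    a = np.deg2rad(np.asarray(az_deg, float))
    return 1e6 * head_radius / c * (np.sin(a) + a)


def sine_ild(az_deg, max_ild: float = 10.0):
    """Synthetic broadband azimuth -> ILD map (dB): max_ild * sin(azimuth)."""
    return max_ild * np.sin(np.deg2rad(np.asarray(az_deg, float)))


def perceptual_weight(unbiased_resp, biased_resp, imposed_bias, cue_map) -> float:
    """Dimensionless perceptual weight of a binaural cue.

    Responses (azimuths, degrees; rear responses are first reflected across
    the coronal plane) are mapped to cue units with ``cue_map`` and the
    azimuth shift is expressed as a cue change:

        weight = mean[ (cue_map(biased) - cue_map(unbiased)) / imposed_bias ]

    A weight of 1 means an imposed cue change of tau shifts the response by
    an azimuth whose natural cue difference is tau; 0 means no effect.
    """
    ub = _reflect_to_front(unbiased_resp)
    bb = _reflect_to_front(biased_resp)
    bias = np.asarray(imposed_bias, float)
    if np.any(bias == 0):
        raise ValueError("imposed bias must be nonzero")
    shift = np.asarray(cue_map(bb), float) - np.asarray(cue_map(ub), float)
    return float(np.mean(shift / bias))


def _logistic(x, top, mid, slope):
    return top / (1.0 + np.exp(-(x - mid) / slope))


def srt(accuracy, snrs, criterion: str | float = "half_max") -> ThresholdResult:
    """Speech reception threshold from accuracy vs. SNR.

    Fits a monotone logistic (floor 0, fitted asymptote) to the psychometric
    function and returns the SNR at criterion. ``criterion='half_max'``
    reads off half the fitted upper asymptote (which is the fitted
    midpoint); a float in (0, 1) requests that absolute proportion correct.
    """
    from scipy.optimize import curve_fit

    acc = np.asarray(accuracy, float)
    x = np.asarray(snrs, float)
    if acc.shape != x.shape or x.size < 4:
        raise ValueError("need accuracy at >= 4 SNR points")
    if np.ptp(acc) < 1e-3:
        return ThresholdResult(np.nan, np.nan, "sigmoid", measurable=False)
    top0 = float(acc.max())
    mid0 = float(x[np.argmin(np.abs(acc - top0 / 2))])
    slope0 = max(np.ptp(x) / 10.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _logistic, x, acc, p0=[top0, mid0, slope0],
            bounds=([1e-6, x.min() - 3 * np.ptp(x), 1e-4],
                    [1.5, x.max() + 3 * np.ptp(x), 10 * np.ptp(x)]),
            maxfev=20000,
        )
    except RuntimeError:
        return ThresholdResult(np.nan, np.nan, "sigmoid", measurable=False)
    top, mid, slope = popt
    if criterion == "half_max":
        return ThresholdResult(0.5, float(mid), "sigmoid-half-max")
    c = float(criterion)
    if not (0 < c < top):
        return ThresholdResult(c, np.nan, "sigmoid", measurable=False)
    thr = mid + slope * np.log(c / (top - c))
    return ThresholdResult(c, float(thr), "sigmoid")


def tfs_benefit(srt_table) -> "pd.DataFrame":
    """Benefit from temporal fine structure, per cutoff channel and noise type.

    ``srt_table`` is a tidy DataFrame with columns ``cutoff_channel``,
    ``noise`` and ``srt`` (dB). The benefit is the leftward SRT shift
    relative to fully vocoded speech: benefit(k) = SRT(0) - SRT(k), so the
    k=0 baseline must be present for every noise type and maps to 0 exactly.
    """
    import pandas as pd

    df = pd.DataFrame(srt_table)
    required = {"cutoff_channel", "noise", "srt"}
    if not required.issubset(df.columns):
        raise ValueError(f"srt_table needs columns {sorted(required)}")
    out = []
    for noise, grp in df.groupby("noise", sort=False):
        base = grp.loc[grp["cutoff_channel"] == 0, "srt"]
        if base.empty:
            raise ValueError(f"missing cutoff_channel=0 baseline for noise {noise!r}")
        b0 = float(base.iloc[0])
        g = grp.copy()
        g["benefit_db"] = b0 - g["srt"]
        out.append(g)
    return pd.concat(out, ignore_index=True)[["cutoff_channel", "noise", "srt", "benefit_db"]]
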