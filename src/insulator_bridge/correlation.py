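"""FCS/FCCS correlation models and the DNA-bridging fraction estimator.

Fluorescence correlation spectroscopy (FCS) analyses the fluctuations of
the fluorescence signal as labeled molecules diffuse through a confocal
detection volume.  The autocorrelation amplitude reports the mean
occupancy ``N`` of the volume and its decay the diffusion time ``tau_D``
(``tau_D = w^2 / 4D`` for lateral waist ``w``).  Dual-color
cross-correlation (FCCS) reports co-diffusion: only particles carrying
both a green and a red label contribute to the cross-correlation
amplitude.

The bridging experiment modeled here mixes two preparations of the same
specific DNA fragment, one labeled green (Cy3B) and one red (atto655), in
equal amounts.  A bridging factor that links two protein-bound DNA
molecules into one complex produces green/red co-diffusion.  Two
corrections stand between the measured relative cross-correlation
amplitude ``A`` and the bridged fraction ``f``:

* random pairing of the two DNA molecules in a bridged complex means that
  at a 50/50 color mix only half of the bridged complexes are two-colored
  (``2 q (1-q)`` for green probability ``q``), and
* incomplete dye labeling (efficiencies ``e_g``, ``e_r``) leaves some
  molecules dark.

The estimator used here is ``f = A / (p_hetero * e_g * e_r)``.

All lag times and diffusion times are in seconds; amplitudes are
dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, InvalidParameterError

__all__ = [
    "CorrelationCurve",
    "DiffusionFit",
    "CrossCorrelationFit",
    "BridgingEstimate",
    "acf_model",
    "ccf_model",
    "fit_acf",
    "fit_ccf",
    "relative_cc_amplitude",
    "bridged_fraction",
    "max_observable_fraction",
]

DEFAULT_STRUCTURE_S = 5.0


@dataclass
class CorrelationCurve:
    """A correlation curve: lag times (s) vs baseline-subtracted G(tau).

    ``lag`` must be strictly increasing and non-negative; a leading
    zero-lag point is allowed (multi-tau correlators produce one) but is
    ignored by the fitting routines, where shot noise dominates.
    ``channel_pair`` is one of ``green_auto``, ``red_auto``, ``cross``.
    """

    lag: np.ndarray
    g: np.ndarray
    channel_pair: str = "green_auto"

    def __post_init__(self):
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.shape != self.g.shape or self.lag.ndim != 1:
            raise InputError("lag and g must be 1-D arrays of equal length")
        if np.any(self.lag < 0) or np.any(np.diff(self.lag) <= 0):
            raise InputError("lag times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise InputError("correlation amplitudes must be finite")
        if self.channel_pair not in ("green_auto", "red_auto", "cross"):
            raise InputError(f"unknown channel_pair {self.channel_pair!r}")

    def __len__(self) -> int:
        return self.lag.size


@dataclass
class DiffusionFit:
    """Parameters of a one-component 3-D diffusion + triplet fit.

    ``n_mean`` is the mean occupancy of the effective volume, ``tau_d``
    the diffusion time (s), ``triplet_frac``/``tau_t`` the triplet-state
    fraction and relaxation time, and ``s`` the (fixed) structure
    parameter, i.e. the axial/lateral waist ratio of the detection volume.
    """

    n_mean: float
    tau_d: float
    triplet_frac: float = 0.0
    tau_t: float = 5e-6
    s: float = DEFAULT_STRUCTURE_S
    tau_d_se: float = np.nan
    n_mean_se: float = np.nan
    rss: float = np.nan

    @property
    def tau_d_ms(self) -> float:
        return self.tau_d * 1e3

    @property
    def g0(self) -> float:
        """Zero-lag amplitude of the diffusion component, ``1/N``."""
        return 1.0 / self.n_mean

    @property
    def g0_total(self) -> float:
        """Total fitted zero-lag amplitude ``(1/N)/(1-T)``, triplet included."""
        return 1.0 / self.n_mean / (1.0 - self.triplet_frac)

    def predict(self, lag) -> np.ndarray:
        return acf_model(lag, self.n_mean, self.tau_d, self.triplet_frac, self.tau_t, self.s)


@dataclass
class CrossCorrelationFit:
    """Amplitude and diffusion time of a cross-correlation fit."""

    amplitude: float
    tau_d: float
    s: float = DEFAULT_STRUCTURE_S
    amplitude_se: float = np.nan
    tau_d_se: float = np.nan
    rss: float = np.nan

    def predict(self, lag) -> np.ndarray:
        return ccf_model(lag, self.amplitude, self.tau_d, self.s)


@dataclass
class BridgingEstimate:
    """Bridged fraction derived from a relative cross-correlation amplitude.

    ``bridged_fraction = cc_amplitude / (hetero_pair_prob * label_eff_green
    * label_eff_red)``, clipped to [0, 1]; ``clipped`` records whether the
    raw estimate exceeded 1.
    """

    cc_amplitude: float
    hetero_pair_prob: float = 0.5
    label_eff_green: float = 0.57
    label_eff_red: float = 0.97
    bridged_fraction: float = np.nan
    clipped: bool = False


def acf_model(lag, n_mean: float, tau_d: float, triplet_frac: float = 0.0,
              tau_t: float = 5e-6, s: float = DEFAULT_STRUCTURE_S):
    """One-component 3-D diffusion autocorrelation with a triplet term.

    ``G(tau) = (1/N) [1 + T/(1-T) exp(-tau/tau_T)]
               (1 + tau/tau_D)^-1 (1 + tau/(s^2 tau_D))^-1/2``

    The detection volume is a 3-D Gaussian with axial/lateral ratio ``s``.
    Without triplet the zero-lag value is ``1/N``; in general it is
    ``(1/N)/(1-T)``.
    """
    if not n_mean > 0:
        raise InvalidParameterError("n_mean must be positive")
    if not tau_d > 0:
        raise InvalidParameterError("tau_d must be positive")
    if not 0 <= triplet_frac < 1:
        raise InvalidParameterError("triplet_frac must be in [0, 1)")
    if triplet_frac > 0 and not tau_t > 0:
        raise InvalidParameterError("tau_t must be positive")
    if not s > 1:
        raise InvalidParameterError("structure parameter s must exceed 1")
    tau = np.asarray(lag, dtype=float)
    diff = 1.0 / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (s * s * tau_d))
    if triplet_frac > 0:
        trip = 1.0 + triplet_frac / (1.0 - triplet_frac) * np.exp(-tau / tau_t)
    else:
        trip = 1.0
    out = trip * diff / n_mean
    return out if np.ndim(out) else float(out)


def ccf_model(lag, amplitude: float, tau_d: float, s: float = DEFAULT_STRUCTURE_S):
    """Cross-correlation of a single co-diffusing (bridged) species.

    ``G_x(tau) = A (1 + tau/tau_D)^-1 (1 + tau/(s^2 tau_D))^-1/2`` --
    no triplet term, since pulsed interleaved excitation separates the
    channels and the cross-correlation of independent triplet blinking
    vanishes.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    if not tau_d > 0:
        raise InvalidParameterError("tau_d must be positive")
    if not s > 1:
        raise InvalidParameterError("structure parameter s must exceed 1")
    tau = np.asarray(lag, dtype=float)
    out = amplitude / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (s * s * tau_d))
    return out if np.ndim(out) else float(out)


def _fit_curve(curve: CorrelationCurve, func, starts, bounds, min_points=20,
               min_decades=3.0):
    """Shared multi-start least-squares machinery for correlation fits."""
    from .binding import _multistart_curve_fit, _param_se  # same machinery

    mask = curve.lag > 0
    lag = curve.lag[mask]
    g = curve.g[mask]
    if lag.size < min_points:
        raise InputError(f"need at least {min_points} positive-lag points")
    if np.log10(lag.max() / lag.min()) < min_decades:
        raise InputError(f"lag range must span at least {min_decades} decades")
    rss, popt, pcov, _ = _multistart_curve_fit(func, lag, g, starts, bounds)
    return rss, popt, _param_se(pcov), lag


def fit_acf(curve: CorrelationCurve, fix_s: float = DEFAULT_STRUCTURE_S) -> DiffusionFit:
    """Fit an autocorrelation curve with the 3-D diffusion + triplet model.

    The structure parameter ``s`` is fixed (default 5, a typical confocal
    calibration value) and ``(N, tau_D, T, tau_T)`` are fitted by a
    deterministic multi-start least squares over a log-spaced grid of
    diffusion-time starts.  The zero-lag point, if present, is excluded:
    it is dominated by shot noise.
    """
    if not fix_s > 1:
        raise InvalidParameterError("structure parameter must exceed 1")
    lag_pos = curve.lag[curve.lag > 0]
    if lag_pos.size == 0:
        raise InputError("curve has no positive lags")

    def func(tau, n_mean, tau_d, trip, tau_t):
        diff = 1.0 / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (fix_s * fix_s * tau_d))
        return (1.0 + trip / (1.0 - trip) * np.exp(-tau / tau_t)) * diff / n_mean

    gmax = float(np.max(curve.g))
    n0 = 1.0 / gmax if gmax > 0 else 1.0
    tau_grid = np.geomspace(lag_pos.min() * 10, lag_pos.max() / 10, 5)
    starts = [(n0, td, t0, 5e-6) for td in tau_grid for t0 in (0.01, 0.3)]
    bounds = (
        [1e-12, lag_pos.min() / 100, 0.0, 1e-8],
        [1e12, lag_pos.max() * 100, 0.9, 1e-2],
    )
    rss, popt, se, _ = _fit_curve(curve, func, starts, bounds)
    return DiffusionFit(
        n_mean=float(popt[0]),
        tau_d=float(popt[1]),
        triplet_frac=float(popt[2]),
        tau_t=float(popt[3]),
        s=fix_s,
        tau_d_se=float(se[1]),
        n_mean_se=float(se[0]),
        rss=rss,
    )


def fit_ccf(curve: CorrelationCurve, fix_s: float = DEFAULT_STRUCTURE_S) -> CrossCorrelationFit:
    """Fit a cross-correlation curve with the single-species model.

    Returns the zero-lag amplitude and diffusion time of the bridged
    species.  A flat, zero curve fits with amplitude ~ 0.
    """
    if not fix_s > 1:
        raise InvalidParameterError("structure parameter must exceed 1")
    lag_pos = curve.lag[curve.lag > 0]
    if lag_pos.size == 0:
        raise InputError("curve has no positive lags")

    def func(tau, amp, tau_d):
        return amp / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (fix_s * fix_s * tau_d))

    a0 = max(float(np.max(curve.g)), 1e-6)
    tau_grid = np.geomspace(lag_pos.min() * 10, lag_pos.max() / 10, 5)
    starts = [(a0, td) for td in tau_grid]
    bounds = ([0.0, lag_pos.min() / 100], [1e12, lag_pos.max() * 100])
    rss, popt, se, _ = _fit_curve(curve, func, starts, bounds)
    return CrossCorrelationFit(
        amplitude=float(popt[0]),
        tau_d=float(popt[1]),
        s=fix_s,
        amplitude_se=float(se[0]),
        tau_d_se=float(se[1]),
        rss=rss,
    )


def relative_cc_amplitude(cross: CorrelationCurve, auto: CorrelationCurve,
                          fix_s: float = DEFAULT_STRUCTURE_S) -> float:
    """Relative cross-correlation amplitude ``A = G_x(0) / G_auto(0)``.

    Both zero-lag values are taken from fitted models (never from the
    noisy shortest lags): the cross curve with :func:`ccf_model`, the
    reference autocorrelation with :func:`acf_model` extrapolated to its
    total zero-lag value ``(1/N)/(1-T)``.  The total (rather than the
    diffusion-only ``1/N``) is used because any fast component the auto
    fit assigns to the triplet term still contributes particles to the
    denominator of the cross-correlation amplitude.

    Note on the choice of reference: with cross- and autocorrelations
    normalized by the mean intensities, ``G_x(0)/G_auto(0)`` equals the
    number of two-color complexes per particle detected in the *other*
    channel.  To quantify the fraction of red-detected complexes that
    co-diffuse with a green partner, pass the **green** autocorrelation as
    ``auto`` (and vice versa).
    """
    x_fit = fit_ccf(cross, fix_s=fix_s)
    a_fit = fit_acf(auto, fix_s=fix_s)
    g0 = a_fit.g0_total
    if not g0 > 0:
        raise InputError("reference autocorrelation has non-positive zero-lag value")
    a = x_fit.amplitude / g0
    if a > 1.0:
        warnings.warn(
            f"relative cross-correlation amplitude {a:.3f} exceeds 1; clipping",
            stacklevel=2,
        )
        a = 1.0
    return float(a)


def bridged_fraction(cc_amplitude: float, hetero_pair_prob: float = 0.5,
                     label_eff_green: float = 0.57,
                     label_eff_red: float = 0.97) -> BridgingEstimate:
    """Bridged fraction from a relative cross-correlation amplitude.

    ``f = A / (p_hetero * e_g * e_r)`` corrects the measured amplitude for
    the two-color pairing ceiling (``p_hetero``, 0.5 at an equal mix) and
    for the green/red labeling efficiencies.  The estimate is clipped to
    [0, 1]; ``clipped`` is set when the raw value exceeded 1.
    """
    if not 0 <= cc_amplitude <= 1:
        raise InvalidParameterError("cc_amplitude must be in [0, 1]")
    if not 0 < hetero_pair_prob <= 1:
        raise InvalidParameterError("hetero_pair_prob must be in (0, 1]")
    if not 0 < label_eff_green <= 1 or not 0 < label_eff_red <= 1:
        raise InvalidParameterError("labeling efficiencies must be in (0, 1]")
    raw = cc_amplitude / (hetero_pair_prob * label_eff_green * label_eff_red)
    clipped = raw > 1.0
    if clipped:
        warnings.warn(
            f"bridged fraction {raw:.3f} exceeds 1; clipping to 1", stacklevel=2
        )
    return BridgingEstimate(
        cc_amplitude=float(cc_amplitude),
        hetero_pair_prob=float(hetero_pair_prob),
        label_eff_green=float(label_eff_green),
        label_eff_red=float(label_eff_red),
        bridged_fraction=min(raw, 1.0),
        clipped=bool(clipped),
    )


def max_observable_fraction(mix_fraction_green: float) -> float:
    """Probability that a randomly paired bridged complex is two-colored.

    With each DNA molecule independently green with probability ``q`` and
    red with ``1-q``, a bridged pair is hetero-colored with probability
    ``2 q (1-q)`` -- at most 0.5, reached at the equal mix ``q = 0.5``.
    Same-color pairs are invisible to the cross-correlation channel, so
    this is the ceiling on the observable bridged fraction.
    """
    q = float(mix_fraction_green)
    if not 0 <= q <= 1:
        raise InvalidParameterError("mix_fraction_green must be in [0, 1]")
    return 2.0 * q * (1.0 - q)
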