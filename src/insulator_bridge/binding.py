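"""Equilibrium models of sequence-specific protein-DNA association.

This module fits fluorescence-anisotropy titrations of a labeled DNA probe
with increasing protein concentration.  Binding of a protein (e.g. an
insulator binding protein such as BEAF32) to a short labeled duplex slows
the rotational diffusion of the probe and raises its anisotropy, so the
titration traces out a binding isotherm in anisotropy units.

Two isotherm shapes are supported:

* ``single_site`` -- the Langmuir isotherm ``f = [P] / (K_D + [P])``,
  appropriate for independent, non-cooperative binding.
* ``hill`` -- the Hill isotherm ``f = [P]^n / (K_D^n + [P]^n)`` with
  half-saturation constant ``K_D`` and cooperativity exponent ``n``;
  ``n > 1`` indicates cooperative (multimeric) binding, and ``n = 1``
  reduces exactly to the single-site form.

Because the probe (typically 2.5 nM) is far below the protein
concentrations titrated (up to 800 nM), ligand depletion is neglected and
free protein is identified with total protein.  Concentrations are in nM
throughout; anisotropy is dimensionless (conventionally reported as
"anisotropy units", i.e. anisotropy x 1000).

Competition experiments (unlabeled competitor displacing a pre-formed
protein-probe complex) are analysed with a three-parameter hyperbolic
decay, and the resulting EC50 is converted to an apparent competitor
constant K_i with a Cheng-Prusoff-type correction.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InputError, InvalidParameterError

__all__ = [
    "BindingIsotherm",
    "BindingFit",
    "CompetitionCurve",
    "single_site_fraction",
    "hill_fraction",
    "anisotropy_model",
    "fit_isotherm",
    "fit_competition",
    "ec50_to_ki",
]

# Deterministic multi-start grids (nM for K_D, dimensionless for n).
_KD_STARTS = (10.0, 30.0, 100.0, 300.0, 1000.0)
_N_STARTS = (0.5, 1.0, 2.0, 4.0)

# Relative rss tolerance below which two starts are considered tied; ties
# are broken toward the lower K_D so the fit is deterministic.
_TIE_RTOL = 1e-9


@dataclass
class BindingIsotherm:
    """A titration series: total protein concentration vs anisotropy.

    Parameters
    ----------
    protein_conc : array of total protein concentrations (nM), strictly
        increasing and non-negative.
    anisotropy : measured anisotropy per concentration (anisotropy units).
    sigma : optional per-point standard deviations (same units as
        ``anisotropy``); used as weights in fitting when given.
    probe_conc : labeled probe concentration (nM), default 2.5.
    label : free-text description of the probe/protein pair.
    """

    protein_conc: np.ndarray
    anisotropy: np.ndarray
    sigma: np.ndarray | None = None
    probe_conc: float = 2.5
    label: str = ""

    def __post_init__(self):
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.protein_conc.ndim != 1:
            raise InputError("protein_conc must be one-dimensional")
        if self.protein_conc.shape != self.anisotropy.shape:
            raise InputError("protein_conc and anisotropy must have equal length")
        if np.any(self.protein_conc < 0):
            raise InputError("protein concentrations must be non-negative")
        if np.any(np.diff(self.protein_conc) <= 0):
            raise InputError("protein concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.anisotropy)):
            raise InputError("anisotropy values must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.anisotropy.shape:
                raise InputError("sigma must match anisotropy length")
            if np.any(self.sigma <= 0):
                raise InputError("sigma values must be positive")
        if not self.probe_conc > 0:
            raise InputError("probe_conc must be positive")

    def __len__(self) -> int:
        return self.protein_conc.size


@dataclass
class BindingFit:
    """Result of fitting a binding isotherm.

    ``kd`` is the half-saturation constant in nM; for the Hill model
    ``hill_n`` is the cooperativity exponent (fixed at 1 for the
    single-site model).  ``r_free`` and ``delta_r`` map the bound fraction
    onto the observable: predicted anisotropy is
    ``r_free + delta_r * fraction_bound``.  Standard errors come from the
    Jacobian at the optimum; ``rss`` is the (weighted, if sigma was
    supplied) residual sum of squares.
    """

    kd: float
    hill_n: float
    r_free: float
    delta_r: float
    model: str
    kd_se: float = np.nan
    n_se: float = np.nan
    r_free_se: float = np.nan
    delta_r_se: float = np.nan
    rss: float = np.nan
    n_points: int = 0
    n_starts_converged: int = 0

    def predict(self, p_total) -> np.ndarray:
        return anisotropy_model(p_total, self.r_free, self.delta_r, self.kd, self.hill_n)


@dataclass
class CompetitionCurve:
    """A competition titration and (after fitting) its EC50 / K_i.

    ``anisotropy`` decreases as unlabeled competitor displaces the protein
    from the labeled probe.  ``labeled_probe_conc`` and ``probe_kd``
    (both nM) feed the Cheng-Prusoff correction of the fitted EC50.
    """

    competitor_conc: np.ndarray
    anisotropy: np.ndarray
    labeled_probe_conc: float = 2.5
    probe_kd: float | None = None
    ec50: float | None = None
    ec50_se: float | None = None
    r0: float | None = None
    r_inf: float | None = None
    ki: float | None = None
    rss: float | None = None

    def __post_init__(self):
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.competitor_conc.shape != self.anisotropy.shape:
            raise InputError("competitor_conc and anisotropy must have equal length")
        if np.any(self.competitor_conc < 0):
            raise InputError("competitor concentrations must be non-negative")
        if self.ec50 is not None and not self.ec50 > 0:
            raise InvalidParameterError("fitted ec50 must be positive")


def single_site_fraction(p_total, kd: float):
    """Fraction of probe bound under the Langmuir single-site isotherm.

    ``f = p / (kd + p)``; monotone non-decreasing in ``p_total`` and equal
    to 0.5 at ``p_total == kd``.
    """
    if not kd > 0:
        raise InvalidParameterError(f"kd must be positive, got {kd}")
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0):
        raise InvalidParameterError("p_total must be non-negative")
    out = p / (kd + p)
    return out if out.ndim else float(out)


def hill_fraction(p_total, kd: float, n: float):
    """Fraction bound under the Hill isotherm ``p^n / (kd^n + p^n)``.

    ``kd`` is the half-saturation constant (``f(kd) = 0.5`` for any ``n``)
    and ``n`` the Hill coefficient; ``n = 1`` reduces to
    :func:`single_site_fraction`.
    """
    if not kd > 0:
        raise InvalidParameterError(f"kd must be positive, got {kd}")
    if not n > 0:
        raise InvalidParameterError(f"hill coefficient must be positive, got {n}")
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0):
        raise InvalidParameterError("p_total must be non-negative")
    # (p/kd)^n form avoids overflow for large kd^n.
    ratio = np.power(p / kd, n)
    with np.errstate(invalid="ignore"):
        out = ratio / (1.0 + ratio)
    out = np.where(np.isinf(ratio), 1.0, out)
    return out if out.ndim else float(out)


def anisotropy_model(p_total, r_free: float, delta_r: float, kd: float, n: float = 1.0):
    """Predicted anisotropy ``r_free + delta_r * hill_fraction(p, kd, n)``.

    At ``p_total = 0`` this returns the free-probe anisotropy ``r_free``;
    at saturation it tends to ``r_free + delta_r``.
    """
    return r_free + delta_r * hill_fraction(p_total, kd, n)


def _weighted_rss(resid: np.ndarray, sigma: np.ndarray | None) -> float:
    if sigma is None:
        return float(np.sum(resid**2))
    return float(np.sum((resid / sigma) ** 2))


def _multistart_curve_fit(func, x, y, starts, bounds, sigma=None, kd_index=None):
    """Run curve_fit from every start; keep the lowest-rss solution.

    Ties (relative rss difference below ``_TIE_RTOL``) are broken toward
    the lower value of the parameter at ``kd_index`` so the result does not
    depend on grid order.
    """
    best = None
    diagnostics = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                func,
                x,
                y,
                p0=p0,
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=bounds,
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            diagnostics.append({"start": tuple(p0), "error": str(exc)})
            continue
        rss = _weighted_rss(y - func(x, *popt), sigma)
        diagnostics.append({"start": tuple(p0), "rss": rss})
        if best is None:
            best = (rss, popt, pcov)
            continue
        best_rss = best[0]
        if rss < best_rss * (1.0 - _TIE_RTOL) - _TIE_RTOL:
            best = (rss, popt, pcov)
        elif abs(rss - best_rss) <= _TIE_RTOL * (1.0 + best_rss) and kd_index is not None:
            if popt[kd_index] < best[1][kd_index]:
                best = (rss, popt, pcov)
    if best is None:
        raise FitFailureError("no start of the multi-start fit converged", diagnostics)
    n_ok = sum(1 for d in diagnostics if "rss" in d)
    return best[0], best[1], best[2], n_ok


def _param_se(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return se


def fit_isotherm(iso: BindingIsotherm, model: str = "hill") -> BindingFit:
    """Weighted nonlinear least-squares fit of a binding isotherm.

    Fits ``(r_free, delta_r, kd)`` for ``model="single_site"`` or
    ``(r_free, delta_r, kd, n)`` for ``model="hill"`` with a deterministic
    multi-start over a fixed grid of ``kd`` (and ``n``) values; the start
    with the lowest residual sum of squares wins, ties broken toward the
    lower ``kd``.  Per-point ``sigma`` from the isotherm, when present,
    weights the fit and scales the reported standard errors.
    """
    if model not in ("single_site", "hill"):
        raise InvalidParameterError(f"unknown model {model!r}")
    x = iso.protein_conc
    y = iso.anisotropy
    n_params = 3 if model == "single_site" else 4
    if np.unique(x).size < 5:
        raise InputError("need at least 5 distinct concentrations to fit an isotherm")
    if x.size < n_params:
        raise InputError("fewer points than parameters")
    if x.min() > 0.05 * x.max():
        warnings.warn(
            "no near-zero concentration point; the free-probe anisotropy is poorly constrained",
            stacklevel=2,
        )

    r0 = float(y[np.argmin(x)])
    dr0 = float(y.max() - y.min()) or 1.0

    if model == "single_site":

        def func(p, r_free, delta_r, kd):
            return r_free + delta_r * (p / (kd + p))

        starts = [(r0, dr0, kd) for kd in _KD_STARTS]
        bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e9])
        kd_index = 2
    else:

        def func(p, r_free, delta_r, kd, n):
            ratio = np.power(np.maximum(p, 0.0) / kd, n)
            return r_free + delta_r * ratio / (1.0 + ratio)

        starts = [(r0, dr0, kd, n) for kd in _KD_STARTS for n in _N_STARTS]
        bounds = ([-np.inf, -np.inf, 1e-9, 1e-3], [np.inf, np.inf, 1e9, 50.0])
        kd_index = 2

    rss, popt, pcov, n_ok = _multistart_curve_fit(
        func, x, y, starts, bounds, sigma=iso.sigma, kd_index=kd_index
    )
    se = _param_se(pcov)
    if model == "single_site":
        return BindingFit(
            kd=float(popt[2]),
            hill_n=1.0,
            r_free=float(popt[0]),
            delta_r=float(popt[1]),
            model=model,
            kd_se=float(se[2]),
            n_se=np.nan,
            r_free_se=float(se[0]),
            delta_r_se=float(se[1]),
            rss=rss,
            n_points=x.size,
            n_starts_converged=n_ok,
        )
    return BindingFit(
        kd=float(popt[2]),
        hill_n=float(popt[3]),
        r_free=float(popt[0]),
        delta_r=float(popt[1]),
        model=model,
        kd_se=float(se[2]),
        n_se=float(se[3]),
        r_free_se=float(se[0]),
        delta_r_se=float(se[1]),
        rss=rss,
        n_points=x.size,
        n_starts_converged=n_ok,
    )


def fit_competition(curve: CompetitionCurve) -> CompetitionCurve:
    """Fit a three-parameter hyperbolic decay to a competition titration.

    The model is ``r(c) = r_inf + (r_0 - r_inf) / (1 + c / EC50)``, whose
    midpoint ``(r_0 + r_inf)/2`` is reached exactly at ``c = EC50``.
    Returns a copy of ``curve`` with ``ec50`` (and its standard error,
    ``r0``, ``r_inf``, ``rss``) filled in; when ``probe_kd`` is set, ``ki``
    is additionally computed via :func:`ec50_to_ki`.  Data that are not
    overall decreasing trigger a warning but the fit is still attempted.
    """
    c = curve.competitor_conc
    y = curve.anisotropy
    if c.size < 5:
        raise InputError("need at least 5 points to fit a competition curve")
    if y[-1] >= y[0]:
        warnings.warn("competition data are not overall decreasing", stacklevel=2)

    def func(cc, r_inf, r0, ec50):
        return r_inf + (r0 - r_inf) / (1.0 + cc / ec50)

    pos = c[c > 0]
    if pos.size:
        grid = np.geomspace(pos.min(), pos.max(), 5)
    else:
        grid = np.array([1.0])
    starts = [(float(y[-1]), float(y[0]), g) for g in grid]
    bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e12])
    rss, popt, pcov, _ = _multistart_curve_fit(func, c, y, starts, bounds, kd_index=2)
    se = _param_se(pcov)
    ec50 = float(popt[2])
    ki = None
    if curve.probe_kd is not None:
        ki = ec50_to_ki(ec50, curve.labeled_probe_conc, curve.probe_kd)
    return replace(
        curve,
        ec50=ec50,
        ec50_se=float(se[2]),
        r_inf=float(popt[0]),
        r0=float(popt[1]),
        ki=ki,
        rss=rss,
    )


def ec50_to_ki(ec50: float, labeled_probe_conc: float, probe_kd: float) -> float:
    """Cheng-Prusoff-type correction of a competition EC50.

    ``K_i = EC50 / (1 + [probe] / K_D(probe))``.  The correction only
    reduces the EC50; with probe concentrations (2.5 nM) far below the
    probe K_D the correction is small and ``K_i ~ EC50``.
    """
    if not ec50 > 0:
        raise InvalidParameterError("ec50 must be positive")
    if labeled_probe_conc < 0:
        raise InvalidParameterError("labeled_probe_conc must be non-negative")
    if not probe_kd > 0:
        raise InvalidParameterError("probe_kd must be positive")
    return ec50 / (1.0 + labeled_probe_conc / probe_kd)
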