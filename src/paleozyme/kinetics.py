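"""Michaelis-Menten kinetics: initial-rate fits, progress-curve fits, efficiencies.

Steady-state parameters (kcat, KM) are estimated either from hyperbolic
saturation curves of initial rates, or — for enzymes showing hysteresis, where
initial rates are unreliable — from entire product progress curves.  The plain
progress-curve model uses the closed-form integrated Michaelis-Menten equation

    P(t) = S0 - KM * W( (S0/KM) * exp((S0 - kcat*E0*t) / KM) )

with W the principal Lambert function, evaluated through the Wright omega
function to stay stable when the exponent overflows.  The product-inhibition
variant integrates

    dP/dt = kcat*E0*(S0-P) / (KM*(1 + P/Ki) + (S0-P))

numerically (competitive inhibition by the product, acting on KM).

Catalytic efficiency kcat/KM is reported in 1/(M*s) with KM given in uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares
from scipy.special import wrightomega
from scipy.stats import norm, spearmanr


@dataclass
class ProgressCurve:
    """Product concentration (uM) over time (s) for one substrate loading."""

    curve_id: str
    times: np.ndarray
    product: np.ndarray
    E0: float  # enzyme concentration, uM
    S0: float  # initial substrate concentration, uM

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.shape != self.product.shape:
            raise ValueError("times and product must have equal length")


@dataclass
class KineticParams:
    """Fitted steady-state parameters with standard errors.

    ``kcat_over_km`` is in 1/(M*s); kcat in 1/s; KM and Ki in uM.  When only
    the linear regime of the saturation curve was observable, ``kcat`` and
    ``km`` are None and ``linear_regime`` is set.
    """

    kcat: float | None = None
    km: float | None = None
    ki: float | None = None
    kcat_over_km: float | None = None
    errors: dict = field(default_factory=dict)
    linear_regime: bool = False
    non_identifiable: bool = False


def sig_round(x: float, digits: int = 2) -> float:
    """Round to the given number of significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def catalytic_efficiency(kcat: float, km_uM: float) -> float:
    """kcat/KM in 1/(M*s) from kcat (1/s) and KM (uM)."""
    if kcat <= 0 or km_uM <= 0:
        raise ValueError("kcat and KM must be positive")
    return kcat / (km_uM * 1e-6)


def integrated_mm_product(t, kcat: float, km: float, E0: float, S0: float):
    """Closed-form product concentration of the plain Michaelis-Menten reaction.

    Uses ``W(e^z) = wrightomega(z)`` so large ``S0/KM`` never overflows.
    """
    if min(kcat, km, E0, S0) <= 0:
        raise ValueError("all kinetic parameters must be positive")
    t = np.asarray(t, dtype=float)
    z = np.log(S0 / km) + (S0 - kcat * E0 * t) / km
    return S0 - km * np.real(wrightomega(z))


def integrated_pi_time(p, kcat: float, km: float, E0: float, S0: float, ki: float):
    """Time at which product p is reached under competitive product inhibition.

    The rate law is separable; integrating gives the implicit solution

        KM*(1 + S0/Ki) * ln(S0/(S0-P)) + (1 - KM/Ki) * P = kcat*E0*t.
    """
    p = np.asarray(p, dtype=float)
    ratio = np.log(S0 / (S0 - p))
    return (km * (1.0 + S0 / ki) * ratio + (1.0 - km / ki) * p) / (kcat * E0)


def integrated_pi_product(t, kcat, km, E0, S0, ki, n_grid=3000):
    """Product vs time under product inhibition, by inverting the implicit
    closed form on a dense monotone grid."""
    head = np.linspace(0.0, 0.9 * S0, n_grid // 2, endpoint=False)
    tail = S0 * (1.0 - np.geomspace(0.1, 1e-13, n_grid // 2))
    pgrid = np.concatenate([head, tail])
    tgrid = integrated_pi_time(pgrid, kcat, km, E0, S0, ki)
    return np.interp(np.asarray(t, dtype=float), tgrid, pgrid)


def _mm_rate(P, kcat, km, E0, S0, ki=None):
    S = np.maximum(S0 - P, 0.0)
    denom = km * (1.0 + P / ki) + S if ki is not None else km + S
    return kcat * E0 * S / denom


def simulate_curve_ode(
    kcat, km, E0, S0, times, ki=None, rtol=1e-9, atol=1e-12
) -> np.ndarray:
    """Numerically integrated product trajectory (oracle for the closed form)."""
    sol = solve_ivp(
        lambda _, p: _mm_rate(p, kcat, km, E0, S0, ki),
        (0.0, float(times[-1])),
        [0.0],
        t_eval=np.asarray(times, dtype=float),
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    return sol.y[0]


# ---------------------------------------------------------------------------
# fitting


def fit_initial_rates(v, s0, E0: float) -> KineticParams:
    """Fit v = kcat*E0*S/(KM+S) to initial rates at substrate loadings s0.

    If the data never approach saturation (max S0 below half the apparent KM),
    only kcat/KM is identifiable; it is then estimated from the slope of the
    linear regime (v = (kcat/KM)*E0*S) and the result flagged.
    """
    v = np.asarray(v, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 rate measurements")
    if np.any(s0 <= 0) or E0 <= 0:
        raise ValueError("concentrations must be positive")

    def hyperbola(S, kcat, km):
        return kcat * E0 * S / (km + S)

    p0 = (max(v.max() / E0, 1e-9), np.median(s0))
    try:
        popt, pcov = curve_fit(hyperbola, s0, v, p0=p0, maxfev=20000)
        kcat, km = popt
        saturated = kcat > 0 and km > 0 and s0.max() >= km / 2.0
    except RuntimeError:
        saturated = False

    if not saturated:
        slope = float(np.sum(v * s0) / np.sum(s0 * s0))  # through-origin LSQ
        eff = slope / E0 * 1e6  # (1/s)/uM -> 1/(M*s)
        return KineticParams(kcat_over_km=eff, linear_regime=True)

    perr = np.sqrt(np.diag(pcov))
    return KineticParams(
        kcat=float(kcat),
        km=float(km),
        kcat_over_km=catalytic_efficiency(kcat, km),
        errors={"kcat": float(perr[0]), "km": float(perr[1])},
    )


def _predict_curves(theta, curves, model):
    p = np.exp(theta)
    out = []
    for c in curves:
        if model == "plain":
            out.append(integrated_mm_product(c.times, p[0], p[1], c.E0, c.S0))
        else:
            out.append(integrated_pi_product(c.times, p[0], p[1], c.E0, c.S0, p[2]))
    return np.concatenate(out)


def fit_progress_curves(
    curves: list[ProgressCurve],
    model: str = "plain",
    n_starts: int = 5,
    condition_threshold: float = 1e8,
) -> KineticParams:
    """Global least-squares fit of (kcat, KM[, Ki]) across all progress curves.

    Parameters are fitted on the log scale (positivity by construction) from
    ``n_starts`` log-spaced initial guesses; the best-loss solution wins.
    Standard errors come from the Jacobian at the optimum; a badly conditioned
    Jacobian flags the result as non-identifiable instead of failing silently.
    """
    if model not in ("plain", "product_inhibition"):
        raise ValueError("model must be 'plain' or 'product_inhibition'")
    if not curves:
        raise ValueError("need at least one progress curve")
    obs = np.concatenate([c.product for c in curves])

    # heuristic scales: initial slope -> kcat, median S0 -> KM
    c0 = curves[0]
    k = max(2, len(c0.times) // 10)
    slope = max((c0.product[k] - c0.product[0]) / (c0.times[k] - c0.times[0]), 1e-9)
    kcat_scale = slope / c0.E0
    km_scale = float(np.median([c.S0 for c in curves]))
    npar = 2 if model == "plain" else 3

    best = None
    for factor in np.logspace(-1, 1, n_starts):
        guess = [kcat_scale * factor, km_scale * factor]
        if npar == 3:
            guess.append(km_scale * factor)
        res = least_squares(
            lambda th: _predict_curves(th, curves, model) - obs,
            np.log(guess),
            method="lm",
            max_nfev=4000,
        )
        if best is None or res.cost < best.cost:
            best = res

    p = np.exp(best.x)
    jac = best.jac
    dof = max(obs.size - npar, 1)
    s2 = 2.0 * best.cost / dof
    jtj = jac.T @ jac
    cond = np.linalg.cond(jtj)
    flagged = bool(cond > condition_threshold)
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(npar, np.nan)
        flagged = True
    se = p * se_log  # delta method back from log scale

    errors = {"kcat": float(se[0]), "km": float(se[1])}
    ki = None
    if npar == 3:
        ki = float(p[2])
        errors["ki"] = float(se[2])
    return KineticParams(
        kcat=float(p[0]),
        km=float(p[1]),
        ki=ki,
        kcat_over_km=catalytic_efficiency(p[0], p[1]),
        errors=errors,
        non_identifiable=flagged,
    )


# ---------------------------------------------------------------------------
# diagnostics and concordance


def runs_test_pvalue(residuals) -> float:
    """Wald-Wolfowitz runs test on residual signs (normal approximation).

    A systematically misfitting model produces long same-sign runs and a
    small p-value.
    """
    signs = np.sign(np.asarray(residuals))
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def rank_concordance(efficiencies: dict, times: dict) -> float:
    """Spearman rank correlation between catalytic efficiency and the time an
    enzyme needs to rescue a deletion strain (shared enzymes only, midranks
    for ties)."""
    shared = sorted(set(efficiencies) & set(times))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared enzymes")
    rho, _ = spearmanr(
        [efficiencies[e] for e in shared], [times[e] for e in shared]
    )
    return float(rho)
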