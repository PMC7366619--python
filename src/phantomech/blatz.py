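"""Two-parameter Blatz hyperelastic model: forward evaluation, per-replicate
nonlinear least-squares fitting, and replicate aggregation.

The Cauchy stress at stretch ratio λ is

    σ₀(λ) = γ/(α+1) · ( λ·exp(α(λ²−1)) − λ⁻²·exp(α(1/λ−1)) )

which is zero at λ = 1 and negative in compression (λ < 1).  Measured
compressive stress magnitudes are negated before fitting so the model's
sign convention is honored; reports show magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, SingularParameterError
from .io import ReplicateSet, StressStrainCurve
from .preprocess import to_stretch

_EXP_LIMIT = 700.0  # exp overflow threshold for float64
_ALPHA_SINGULAR_MARGIN = 1e-6

#: multi-start initial values spanning the empirically observed range
DEFAULT_ALPHA_STARTS = (-15.0, -5.0, 0.5, 1.0, 2.0, 5.0)
DEFAULT_GAMMA_STARTS = (1.0, 10.0, 100.0)

DEFAULT_BOUNDS = ((-50.0, 1e-8), (50.0, 1e4))  # ((α_lo, γ_lo), (α_hi, γ_hi))

QUANTILE_LEVELS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class BlatzParams:
    """Material parameters: dimensionless exponent α and stress scale γ (kPa)."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.gamma)):
            raise ValueError("alpha and gamma must be finite")
        if abs(self.alpha + 1.0) < _ALPHA_SINGULAR_MARGIN:
            raise SingularParameterError("alpha = -1 makes the model singular")


@dataclass
class BlatzFit:
    params: BlatzParams
    sse: float
    replicate_id: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


@dataclass
class BlatzSummary:
    """Replicate-aggregated parameters for one mixture."""

    alpha_mean: float
    alpha_sd: float
    gamma_mean: float
    gamma_sd: float
    alpha_quantiles: dict[float, float]
    gamma_quantiles: dict[float, float]
    n_replicates: int
    material: str = ""
    dilution_pct: float = 0.0


def blatz_stress(lam, params: BlatzParams):
    """Evaluate the model Cauchy stress σ₀(λ) in kPa.

    Accepts scalar or array λ > 0.  Negative in compression (λ < 1), zero
    at λ = 1.  Raises on λ ≤ 0, α = −1 (via BlatzParams) and on exponent
    overflow.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be > 0")
    a, g = params.alpha, params.gamma
    e1 = a * (lam**2 - 1.0)
    e2 = a * (1.0 / lam - 1.0)
    if np.any(np.maximum(e1, e2) > _EXP_LIMIT):
        bad = float(np.atleast_1d(lam)[np.argmax(np.maximum(e1, e2))])
        raise OverflowError(
            f"exponential overflow in Blatz stress at lambda={bad:g}, alpha={a:g}"
        )
    out = g / (a + 1.0) * (lam * np.exp(e1) - lam**-2 * np.exp(e2))
    return float(out) if out.ndim == 0 else out


def _safe_model(lam: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """Model evaluation for the optimizer: non-finite values become huge."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        denom = alpha + 1.0
        if abs(denom) < _ALPHA_SINGULAR_MARGIN:
            denom = np.sign(denom or 1.0) * _ALPHA_SINGULAR_MARGIN
        out = gamma / denom * (
            lam * np.exp(np.minimum(alpha * (lam**2 - 1.0), _EXP_LIMIT))
            - lam**-2 * np.exp(np.minimum(alpha * (1.0 / lam - 1.0), _EXP_LIMIT))
        )
    return np.nan_to_num(out, nan=1e12, posinf=1e12, neginf=-1e12)


def fit_blatz(
    curve: StressStrainCurve,
    init: BlatzParams | None = None,
    bounds=DEFAULT_BOUNDS,
    alpha_starts=DEFAULT_ALPHA_STARTS,
    gamma_starts=DEFAULT_GAMMA_STARTS,
    use_true_stress: bool = False,
) -> BlatzFit:
    """Least-squares fit of (α, γ) to one replicate.

    The observed positive stress magnitudes are negated (compression is
    signed negative in the model).  A multi-start grid over
    ``alpha_starts × gamma_starts`` (plus ``init`` when given) guards
    against the model's local optima; the best converged start wins.

    Parameters
    ----------
    use_true_stress : bool
        When True, convert the measured nominal stress to incompressible
        true stress (σ_true = λ·σ_nominal) before fitting.
    """
    lam = to_stretch(curve.strain)
    sigma = -curve.stress  # signed compressive stress
    if use_true_stress:
        sigma = lam * sigma

    if np.allclose(sigma, 0.0):
        warnings.warn(
            "all-zero stress data: objective is flat in alpha; gamma -> 0",
            stacklevel=2,
        )
        return BlatzFit(
            params=BlatzParams(alpha=0.0, gamma=bounds[0][1]),
            sse=0.0,
            replicate_id=curve.replicate_id,
            converged=True,
        )

    starts = [(a, g) for a in alpha_starts for g in gamma_starts]
    if init is not None:
        starts.insert(0, (init.alpha, init.gamma))
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    def residuals(theta):
        return _safe_model(lam, theta[0], theta[1]) - sigma

    best = None
    for a0, g0 in starts:
        x0 = np.clip([a0, g0], lo, hi)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1]:
            best = (res.x, sse)
    if best is None:
        raise ConvergenceError(
            f"Blatz fit failed for replicate {curve.replicate_id!r}: "
            "no start converged"
        )
    (alpha, gamma), sse = best
    at_bound = np.any(np.isclose([alpha, gamma], lo, atol=1e-9)) or np.any(
        np.isclose([alpha, gamma], hi, atol=1e-9)
    )
    if at_bound:
        warnings.warn(
            f"Blatz parameter estimate pinned at a bound: alpha={alpha:g}, "
            f"gamma={gamma:g}",
            stacklevel=2,
        )
    return BlatzFit(
        params=BlatzParams(alpha=float(alpha), gamma=float(gamma)),
        sse=sse,
        replicate_id=curve.replicate_id,
        converged=True,
    )


def fit_blatz_replicates(
    replicates: ReplicateSet, **kwargs
) -> tuple[list[BlatzFit], BlatzSummary]:
    """Fit every replicate in a set and aggregate."""
    fits = [fit_blatz(c, **kwargs) for c in replicates.curves]
    summary = summarize_blatz(fits)
    summary.material = replicates.material
    summary.dilution_pct = replicates.dilution_pct
    return fits, summary


def summarize_blatz(fits) -> BlatzSummary:
    """Mean, sample SD (n−1) and empirical quantiles over converged fits."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged Blatz fits to aggregate")
    alphas = np.array([f.params.alpha for f in converged])
    gammas = np.array([f.params.gamma for f in converged])
    n = alphas.size

    def sd(v):
        return float(v.std(ddof=1)) if n > 1 else 0.0

    def quants(v):
        return {q: float(np.quantile(v, q)) for q in QUANTILE_LEVELS}

    return BlatzSummary(
        alpha_mean=float(alphas.mean()),
        alpha_sd=sd(alphas),
        gamma_mean=float(gammas.mean()),
        gamma_sd=sd(gammas),
        alpha_quantiles=quants(alphas),
        gamma_quantiles=quants(gammas),
        n_replicates=n,
    )
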