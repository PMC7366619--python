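"""Segmented linear regression for low/high-strain compressive moduli.

Fits a continuous piecewise-linear model with three change points to
pooled stress-strain data by iterative linearization: at each step the
stress is regressed on {strain, hinge terms (strain − ψ_k)_+, and signed
gap indicators}, and each change point is updated by ψ_k ← ψ_k + γ̂_k/β̂_k
until the updates vanish.  Bootstrap restarting (residual resampling with
fixed regressors) escapes local optima.  The low-strain modulus E1 is the
slope of the first segment; the high-strain modulus E2 is the slope of
the third segment (between the second and third change points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InsufficientDataError
from .io import ReplicateSet, StressStrainCurve
from .preprocess import PreprocessConfig, common_truncate, pool

DEFAULT_PSI0 = (0.30, 0.40, 0.60)
MIN_FIT_POINTS = 8


def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 − SS_res / SS_tot.

    SS_tot is taken about the mean of ``observed``.  Raises ValueError
    when ``observed`` is constant (R² undefined).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must share length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class SegmentedFit:
    """Result of one segmented-regression run.

    ``psi`` holds the three change points (strain fractions) and
    ``psi_se`` their standard errors.  ``slopes`` holds the four segment
    slopes in kPa per unit strain, first segment first.
    """

    psi: np.ndarray
    psi_se: np.ndarray
    slopes: np.ndarray
    intercept: float
    r2: float
    sse: float
    seed: int
    converged: bool
    n_iter: int
    degenerate: bool = False

    @property
    def e1(self) -> float:
        """Toe slope (segment 1), kPa."""
        return float(self.slopes[0])

    @property
    def e2(self) -> float:
        """Post-heel slope (segment 3, between ψ₂ and ψ₃), kPa."""
        return float(self.slopes[2])

    def predict(self, strain) -> np.ndarray:
        x = np.asarray(strain, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for k, p in enumerate(self.psi):
            y = y + (self.slopes[k + 1] - self.slopes[k]) * np.clip(x - p, 0, None)
        return y


@dataclass
class ModuliEstimate:
    """Seed-averaged moduli for one mixture."""

    material: str
    dilution_pct: float
    E1: float
    E2: float
    E1_sd: float
    E2_sd: float
    psi_mean: np.ndarray
    psi_se: np.ndarray
    r2: float
    fits: list[SegmentedFit] = field(default_factory=list)
    coverage_ok: bool = True

    @property
    def n_runs(self) -> int:
        return len(self.fits)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, StressStrainCurve):
        return data.strain, data.stress
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _design(x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Linearized design: [1, x, (x−ψ_k)_+, −I(x>ψ_k)]."""
    U = np.clip(x[:, None] - psi[None, :], 0.0, None)
    V = -(x[:, None] > psi[None, :]).astype(float)
    return np.column_stack([np.ones_like(x), x, U, V])


def _constrained_fit(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """Continuous piecewise-linear least squares at fixed change points."""
    X = np.column_stack(
        [np.ones_like(x), x, np.clip(x[:, None] - psi[None, :], 0.0, None)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    sse = float(np.sum((y - fitted) ** 2))
    slopes = np.cumsum(np.concatenate(([coef[1]], coef[2:])))
    return coef[0], slopes, fitted, sse


#: minimum data points strictly inside every segment; fewer leaves a
#: segment slope undetermined or wildly unstable
MIN_SEG_POINTS = 2


def _valid_psi(psi: np.ndarray, x: np.ndarray) -> bool:
    if not np.all(np.diff(psi) > 0):
        return False
    counts = np.diff(np.searchsorted(x, np.concatenate(([-np.inf], psi, [np.inf]))))
    return bool(np.all(counts >= MIN_SEG_POINTS))


class _IterationFailure(Exception):
    pass


def _iterate(
    x: np.ndarray,
    y: np.ndarray,
    psi: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """One linearization run from starting change points ``psi``.

    Returns (psi, psi_se, n_iter, converged).  Raises _IterationFailure
    when the change points collapse or leave the data range even after
    step halving.
    """
    n = x.size
    psi = psi.astype(float).copy()
    eps = 1e-12
    converged = False
    # the linearization is not a descent method: remember the best change
    # points visited, judged by the true (constrained-fit) objective
    best_psi = psi.copy()
    best_sse = _constrained_fit(x, y, psi)[3]
    for it in range(1, max_iter + 1):
        X = _design(x, psi)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        beta = coef[2:5]
        gamma = coef[5:8]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(
                np.abs(beta) > eps,
                gamma / beta,
                np.where(np.abs(gamma) <= eps, 0.0, np.inf),
            )
        if not np.all(np.isfinite(delta)):
            raise _IterationFailure("gap update diverged (flat segment slope)")
        # step-halving keeps the change points ordered and interior
        step = 1.0
        for _ in range(40):
            cand = psi + step * delta
            if _valid_psi(cand, x):
                break
            step *= 0.5
        else:
            raise _IterationFailure("change points left the data range")
        psi = cand
        sse = _constrained_fit(x, y, psi)[3]
        if sse < best_sse:
            best_sse, best_psi = sse, psi.copy()
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    # standard errors from the linearized model at the best visited psi
    X = _design(x, best_psi)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    beta = coef[2:5]
    resid = y - X @ coef
    dof = max(n - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_gamma = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv)[5:8], 0, None))
    psi_se = se_gamma / np.maximum(np.abs(beta), eps)
    return best_psi, psi_se, it, converged


def _quantile_starts(x: np.ndarray, n_starts: int) -> list[np.ndarray]:
    """Additional starting triples drawn from data quantiles."""
    from itertools import combinations

    levels = (0.12, 0.25, 0.38, 0.5, 0.62, 0.75, 0.88)
    qs = np.quantile(x, levels)
    starts = []
    for tri in combinations(qs, 3):
        psi = np.asarray(tri)
        if np.all(np.diff(psi) > 0):
            starts.append(psi)
        if len(starts) >= n_starts:
            break
    return starts


def fit_segmented(
    data,
    psi0=DEFAULT_PSI0,
    seed: int = 0,
    n_boot: int = 10,
    tol: float = 1e-8,
    max_iter: int = 100,
    n_jitter: int = 10,
    jitter_scale: float = 0.05,
    n_starts: int = 1,
) -> SegmentedFit:
    """Fit a 4-segment continuous piecewise-linear model.

    Parameters
    ----------
    data : StressStrainCurve or (strain, stress) arrays
        Pooled regression data; duplicate strain values are allowed.
    psi0 : sequence of 3 floats
        Initial change points on the strain axis.
    seed : int
        Seeds the bootstrap resampling and jittered restarts.
    n_boot : int
        Number of bootstrap-restart resamples (0 disables restarting).
    n_jitter : int
        Jittered re-starts attempted when an iteration run fails.
    jitter_scale : float
        Jitter standard deviation as a fraction of the strain range.

    Raises
    ------
    ConvergenceError
        When the initial run and every jittered restart fail.
    """
    x, y = _as_xy(data)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"segmented fit needs >= {MIN_FIT_POINTS} points, got {x.size}"
        )
    psi0 = np.asarray(psi0, dtype=float)
    if psi0.size != 3 or np.any(np.diff(psi0) <= 0):
        raise ValueError("psi0 must be three strictly increasing change points")
    if x[-1] <= psi0[-1]:
        raise ValueError(
            f"data must span beyond max(psi0)={psi0[-1]}, max strain {x[-1]}"
        )
    rng = np.random.default_rng(seed)
    span = x[-1] - x[0]

    def run(start_psi):
        return _iterate(x, y, start_psi, tol=tol, max_iter=max_iter)

    # candidate starting triples: psi0 first, then data-quantile triples
    # (multi-start), then jittered copies of psi0 as a fallback
    starts: list[np.ndarray] = [psi0]
    starts += _quantile_starts(x, n_starts - 1)
    for _ in range(n_jitter):
        starts.append(
            np.sort(
                np.clip(
                    psi0 + rng.normal(0.0, jitter_scale * span, size=3),
                    x[1] + 1e-9,
                    x[-2] - 1e-9,
                )
            )
        )

    best = None
    last_err: Exception | None = None
    n_ok = 0
    for k, start in enumerate(starts):
        if not _valid_psi(start, x):
            continue
        try:
            psi, psi_se, n_iter, converged = run(start)
        except _IterationFailure as exc:
            last_err = exc
            continue
        n_ok += 1
        intercept, slopes, fitted, sse = _constrained_fit(x, y, psi)
        if best is None or sse < best[7] - 1e-12 * max(best[7], 1.0):
            best = (psi, psi_se, n_iter, converged, intercept, slopes, fitted, sse)
        # jittered fallbacks beyond the requested starts only run on failure
        if n_ok >= max(n_starts, 1):
            break
    if best is None:
        raise ConvergenceError(
            f"segmented fit failed from every starting point: {last_err}",
            last_state={"psi0": psi0, "seed": seed},
        )

    # bootstrap restarting: refit on residual-resampled data, then use the
    # resulting change points as fresh starting values on the real data
    resid = y - fitted
    for _ in range(n_boot):
        y_boot = best[6] + rng.choice(resid, size=resid.size, replace=True)
        try:
            psi_b, _, _, _ = _iterate(x, y_boot, best[0], tol=tol, max_iter=max_iter)
            cand = _iterate(x, y, psi_b, tol=tol, max_iter=max_iter)
        except _IterationFailure:
            continue
        c_psi, c_se, c_it, c_conv = cand
        c_int, c_slopes, c_fitted, c_sse = _constrained_fit(x, y, c_psi)
        if c_sse < best[7] - 1e-12 * max(best[7], 1.0):
            best = (c_psi, c_se, c_it, c_conv, c_int, c_slopes, c_fitted, c_sse)
            resid = y - c_fitted

    psi, psi_se, n_iter, converged, intercept, slopes, fitted, sse = best
    degenerate = bool(np.any(np.abs(np.diff(slopes)) <= 1e-8 * np.max(
        np.abs(slopes) + 1e-30)))
    if degenerate:
        warnings.warn(
            "adjacent segment slopes are (near-)equal: change point(s) "
            "degenerate / unidentifiable",
            stacklevel=2,
        )
    return SegmentedFit(
        psi=psi,
        psi_se=psi_se,
        slopes=slopes,
        intercept=float(intercept),
        r2=r_squared(y, fitted),
        sse=sse,
        seed=seed,
        converged=converged,
        n_iter=n_iter,
        degenerate=degenerate,
    )


def estimate_moduli(
    replicates: ReplicateSet,
    cfg: PreprocessConfig = PreprocessConfig(),
    psi0=DEFAULT_PSI0,
    n_runs: int = 10,
    n_boot: int = 10,
    base_seed: int = 0,
) -> ModuliEstimate:
    """Seed-averaged moduli from pooled replicates.

    Pools the (common-truncated) replicates and runs :func:`fit_segmented`
    with seeds ``base_seed .. base_seed + n_runs − 1``.  E1 is the mean of
    the first-segment slopes and E2 the mean of the third-segment slopes
    across runs.
    """
    truncated = common_truncate(replicates, cfg)
    x, y = pool(truncated)
    fits: list[SegmentedFit] = []
    failures = 0
    for i in range(n_runs):
        try:
            fits.append(
                fit_segmented(
                    (x, y), psi0=psi0, seed=base_seed + i, n_boot=n_boot
                )
            )
        except ConvergenceError:
            failures += 1
    if failures * 2 >= n_runs:
        raise ConvergenceError(
            f"{failures}/{n_runs} segmented-regression runs failed to converge"
        )
    e1s = np.array([f.e1 for f in fits])
    e2s = np.array([f.e2 for f in fits])
    psis = np.vstack([f.psi for f in fits])
    n = len(fits)
    return ModuliEstimate(
        material=replicates.material,
        dilution_pct=replicates.dilution_pct,
        E1=float(e1s.mean()),
        E2=float(e2s.mean()),
        E1_sd=float(e1s.std(ddof=1)) if n > 1 else 0.0,
        E2_sd=float(e2s.std(ddof=1)) if n > 1 else 0.0,
        psi_mean=psis.mean(axis=0),
        psi_se=(
            psis.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(3)
        ),
        r2=float(np.mean([f.r2 for f in fits])),
        fits=fits,
        coverage_ok=truncated.coverage_ok,
    )
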