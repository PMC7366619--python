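"""Curve canonicalization ahead of fitting.

Handles the stretch-ratio conversion, the common-maximum truncation rule
for replicate sets, and pooling of replicates into a single regression
data set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import ReplicateSet, StressStrainCurve


@dataclass(frozen=True)
class PreprocessConfig:
    """Truncation and fitting-window settings.

    ``e1_coverage_strain`` is the strain the low-strain modulus window is
    expected to cover; falling short triggers a warning, not an abort.
    ``e1_fit_limit_strain`` caps the standalone low-strain linear check;
    it does not restrict the segmented-fit domain.
    """

    e1_coverage_strain: float = 0.35
    e1_fit_limit_strain: float = 0.33
    truncate_to_common_max: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.e1_fit_limit_strain <= self.e1_coverage_strain < 1):
            raise ValueError(
                "require 0 < e1_fit_limit_strain <= e1_coverage_strain < 1, "
                f"got {self.e1_fit_limit_strain}, {self.e1_coverage_strain}"
            )


def to_stretch(strain):
    """Convert nominal compressive strain to the stretch ratio λ = 1 − ε.

    Accepts scalars or arrays; strain must lie in ``[0, 1)`` so that
    λ ∈ (0, 1].
    """
    strain = np.asarray(strain, dtype=float)
    if np.any(strain >= 1):
        raise ValueError("strain >= 1 has no stretch ratio (specimen annihilated)")
    if np.any(strain < 0):
        raise ValueError("negative compressive strain")
    lam = 1.0 - strain
    return float(lam) if lam.ndim == 0 else lam


def common_truncate(
    replicates: ReplicateSet, cfg: PreprocessConfig = PreprocessConfig()
) -> ReplicateSet:
    """Truncate all replicates at the smallest per-curve maximum strain.

    When the common cutoff falls below ``cfg.e1_coverage_strain`` a
    warning is emitted and ``coverage_ok`` is cleared on the returned set.
    Idempotent.  The low-strain fitting window (``e1_window``) is the
    smaller of the cutoff and ``cfg.e1_fit_limit_strain``.
    """
    # reuse a previously recorded cutoff so the operation is idempotent
    # even when replicate strain grids do not share the cutoff value
    if replicates.cutoff is not None:
        cutoff = replicates.cutoff
    else:
        cutoff = min(c.max_strain for c in replicates.curves)
    coverage_ok = cutoff >= cfg.e1_coverage_strain
    if not coverage_ok:
        warnings.warn(
            f"common maximum strain {cutoff:.3f} is below the coverage "
            f"requirement {cfg.e1_coverage_strain:.2f}; proceeding with the "
            "reduced range for all samples",
            stacklevel=2,
        )
    if cfg.truncate_to_common_max:
        curves = [c.truncated(cutoff) for c in replicates.curves]
    else:
        curves = list(replicates.curves)
    return replace(
        replicates,
        curves=curves,
        cutoff=cutoff,
        coverage_ok=coverage_ok,
        e1_window=min(cutoff, cfg.e1_fit_limit_strain),
    )


def pool(replicates: ReplicateSet) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all replicate points, sorted by strain.

    Duplicate strain values are retained — the result is regression data,
    not a function-valued curve.  Returns ``(strain, stress)`` arrays.
    """
    strain = np.concatenate([c.strain for c in replicates.curves])
    stress = np.concatenate([c.stress for c in replicates.curves])
    order = np.argsort(strain, kind="stable")
    return strain[order], stress[order]


def pooled_curve_label(replicates: ReplicateSet) -> str:
    return f"{replicates.material}_{replicates.dilution_pct:g}pct_pooled"
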