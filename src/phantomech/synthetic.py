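"""Synthetic stress-strain generators with known ground truth.

Two families: forward-evaluated Blatz curves, and toe/heel/post-heel
curves that are linear with slope E1 up to the heel, linear with slope E2
after it, and C¹ cubic-Hermite smoothed across the heel.  Noise is
multiplicative + additive Gaussian, clipped at zero stress, drawn from
``numpy.random.default_rng`` (PCG64) so fixtures are reproducible across
platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .blatz import BlatzParams, blatz_stress
from .io import ReplicateSet, StressStrainCurve, write_curve


@dataclass(frozen=True)
class BilinearTruth:
    """Ground truth for a toe/heel/post-heel curve.

    ``heel`` selects the transition shape: ``"cubic"`` is a C¹ Hermite
    blend; ``"linear"`` is a straight ramp at the mean slope (E1+E2)/2,
    making the whole curve continuous piecewise-linear — the shape the
    segmented estimator can recover exactly.
    """

    E1: float  # toe slope, kPa
    E2: float  # post-heel slope, kPa
    heel_start: float  # strain fraction
    heel_end: float  # strain fraction
    heel: str = "cubic"

    def __post_init__(self) -> None:
        if self.heel not in ("cubic", "linear"):
            raise ValueError("heel must be 'cubic' or 'linear'")


@dataclass(frozen=True)
class SyntheticSpec:
    kind: Literal["blatz", "bilinear"]
    truth: BlatzParams | BilinearTruth
    strain_max: float = 0.70
    n_points: int = 200
    noise_rel: float = 0.02
    noise_abs: float = 0.05
    n_replicates: int = 5
    truth_jitter: float = 0.02
    seed: int = 0
    material: str = "SYNTH"
    dilution_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.strain_max < 1):
            raise ValueError("strain_max must lie in (0, 1)")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.noise_rel < 0 or self.noise_abs < 0 or self.truth_jitter < 0:
            raise ValueError("noise/jitter parameters must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.kind == "bilinear":
            if not isinstance(self.truth, BilinearTruth):
                raise ValueError("kind='bilinear' requires BilinearTruth")
            t = self.truth
            if not (0 < t.heel_start <= t.heel_end < self.strain_max):
                raise ValueError(
                    "require 0 < heel_start <= heel_end < strain_max, got "
                    f"{t.heel_start}, {t.heel_end}, {self.strain_max}"
                )
        elif self.kind == "blatz":
            if not isinstance(self.truth, BlatzParams):
                raise ValueError("kind='blatz' requires BlatzParams")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")


def bilinear_stress(strain, truth: BilinearTruth) -> np.ndarray:
    """Noise-free toe/heel/post-heel stress magnitude.

    Linear (slope E1) below the heel, linear (slope E2) above it, cubic
    Hermite across ``[heel_start, heel_end]`` matching both boundary
    values and slopes.  Degenerates to a single kink when
    ``heel_start == heel_end``.
    """
    strain = np.asarray(strain, dtype=float)
    a, b, E1, E2 = truth.heel_start, truth.heel_end, truth.E1, truth.E2
    y_a = E1 * a
    h = b - a
    # heel endpoint value chosen so the heel's mean slope is (E1+E2)/2
    y_b = y_a + 0.5 * (E1 + E2) * h
    out = np.where(strain <= a, E1 * strain, 0.0)
    post = strain >= b
    out = np.where(post, y_b + E2 * (strain - b), out)
    mid = (strain > a) & (strain < b)
    if np.any(mid):
        if truth.heel == "linear":
            out[mid] = y_a + 0.5 * (E1 + E2) * (strain[mid] - a)
        else:
            t = (strain[mid] - a) / h
            h00 = 2 * t**3 - 3 * t**2 + 1
            h10 = t**3 - 2 * t**2 + t
            h01 = -2 * t**3 + 3 * t**2
            h11 = t**3 - t**2
            out[mid] = h00 * y_a + h10 * h * E1 + h01 * y_b + h11 * h * E2
    return out


def _apply_noise(
    stress: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_rel == 0 and spec.noise_abs == 0:
        return stress
    noisy = stress * (1.0 + rng.normal(0.0, spec.noise_rel, stress.size))
    noisy = noisy + rng.normal(0.0, spec.noise_abs, stress.size)
    return np.clip(noisy, 0.0, None)


def _grid(spec: SyntheticSpec) -> np.ndarray:
    return np.linspace(0.0, spec.strain_max, spec.n_points)


def gen_blatz_curve(
    spec: SyntheticSpec, replicate_id: str = "r1", seed: int | None = None
) -> StressStrainCurve:
    """Forward-evaluated Blatz curve with seeded noise."""
    if spec.kind != "blatz" or not isinstance(spec.truth, BlatzParams):
        raise ValueError("spec.kind must be 'blatz' with BlatzParams truth")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    strain = _grid(spec)
    stress = np.abs(blatz_stress(1.0 - strain, spec.truth))
    return StressStrainCurve(
        strain=strain,
        stress=_apply_noise(stress, spec, rng),
        material=spec.material,
        dilution_pct=spec.dilution_pct,
        replicate_id=replicate_id,
    )


def gen_bilinear_curve(
    spec: SyntheticSpec, replicate_id: str = "r1", seed: int | None = None
) -> StressStrainCurve:
    """Toe/heel/post-heel curve with seeded noise."""
    if spec.kind != "bilinear" or not isinstance(spec.truth, BilinearTruth):
        raise ValueError("spec.kind must be 'bilinear' with BilinearTruth truth")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    strain = _grid(spec)
    stress = bilinear_stress(strain, spec.truth)
    return StressStrainCurve(
        strain=strain,
        stress=_apply_noise(stress, spec, rng),
        material=spec.material,
        dilution_pct=spec.dilution_pct,
        replicate_id=replicate_id,
    )


def _jittered_truth(spec: SyntheticSpec, rng: np.random.Generator):
    """Inter-replicate truth jitter: multiplicative on scale parameters."""
    if spec.truth_jitter == 0:
        return spec.truth
    if isinstance(spec.truth, BlatzParams):
        return BlatzParams(
            alpha=spec.truth.alpha * (1.0 + rng.normal(0.0, spec.truth_jitter)),
            gamma=spec.truth.gamma * (1.0 + rng.normal(0.0, spec.truth_jitter)),
        )
    return replace(
        spec.truth,
        E1=spec.truth.E1 * (1.0 + rng.normal(0.0, spec.truth_jitter)),
        E2=spec.truth.E2 * (1.0 + rng.normal(0.0, spec.truth_jitter)),
    )


def gen_replicate_set(spec: SyntheticSpec) -> tuple[ReplicateSet, list]:
    """Generate ``spec.n_replicates`` curves with independent noise.

    Replicate i uses noise seed ``spec.seed + i`` and a small
    multiplicative jitter on the truth parameters (seeded separately).
    Returns the set and the per-replicate truth records.
    """
    jitter_rng = np.random.default_rng((spec.seed, 0x7EE7))
    gen = gen_blatz_curve if spec.kind == "blatz" else gen_bilinear_curve
    curves, truths = [], []
    for i in range(spec.n_replicates):
        truth_i = _jittered_truth(spec, jitter_rng)
        spec_i = replace(spec, truth=truth_i)
        curves.append(gen(spec_i, replicate_id=f"r{i + 1}", seed=spec.seed + i))
        truths.append(truth_i)
    rset = ReplicateSet(
        material=spec.material, dilution_pct=spec.dilution_pct, curves=curves
    )
    return rset, truths


def write_fixture_directory(
    spec: SyntheticSpec, directory: str | Path
) -> tuple[ReplicateSet, Path]:
    """Write a replicate set as TXT files plus a key=value truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rset, truths = gen_replicate_set(spec)
    for curve in rset:
        name = f"{curve.material}_{curve.dilution_pct:g}_{curve.replicate_id}.txt"
        write_curve(curve, directory / name)
    lines = [f"kind={spec.kind}", f"seed={spec.seed}"]
    for i, t in enumerate(truths, start=1):
        if isinstance(t, BlatzParams):
            lines.append(f"r{i}.alpha={t.alpha!r}")
            lines.append(f"r{i}.gamma={t.gamma!r}")
        else:
            lines.append(f"r{i}.E1={t.E1!r}")
            lines.append(f"r{i}.E2={t.E2!r}")
            lines.append(f"r{i}.heel_start={t.heel_start!r}")
            lines.append(f"r{i}.heel_end={t.heel_end!r}")
    truth_path = directory / f"{spec.material}_{spec.dilution_pct:g}_truth.meta"
    truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return rset, truth_path


def read_truth_sidecar(path: str | Path) -> dict:
    """Parse a key=value truth sidecar back into a flat dict."""
    out: dict[str, object] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, value = line.split("=", 1)
        try:
            out[key] = float(value)
        except ValueError:
            out[key] = value
    return out
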