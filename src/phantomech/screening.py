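"""Mixture screening against target compressive moduli, and the pipeline
driver that ties loading, preprocessing, moduli estimation, Blatz fitting
and ranking together from a single configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .blatz import BlatzParams, fit_blatz_replicates
from .errors import PhantomechError
from .io import load_replicates
from .preprocess import PreprocessConfig
from .segmented import DEFAULT_PSI0, ModuliEstimate, estimate_moduli
from .synthetic import BilinearTruth, SyntheticSpec, gen_replicate_set

logger = logging.getLogger("phantomech")


@dataclass(frozen=True)
class ModuliTarget:
    """Kidney-cortex elastic targets: 20 kPa at low strain, 500 kPa at high."""

    E1_target: float = 20.0
    E2_target: float = 500.0
    E1_range: tuple[float, float] = (13.6, 25.8)

    def __post_init__(self) -> None:
        if self.E1_target <= 0 or self.E2_target <= 0:
            raise ValueError("targets must be > 0")
        lo, hi = self.E1_range
        if not (lo <= self.E1_target <= hi):
            raise ValueError(
                f"E1_target {self.E1_target} outside E1_range {self.E1_range}"
            )


@dataclass
class MixtureScore:
    material: str
    dilution_pct: float
    E1: float
    E2: float
    distance: float
    E1_within_range: bool


@dataclass
class ScreeningResult:
    """Mixtures ranked by ascending distance to the target moduli."""

    ranking: list[MixtureScore] = field(default_factory=list)
    target: ModuliTarget = field(default_factory=ModuliTarget)

    @property
    def best(self) -> MixtureScore:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "material": s.material,
                    "dilution_pct": s.dilution_pct,
                    "E1_kPa": s.E1,
                    "E2_kPa": s.E2,
                    "distance": s.distance,
                    "E1_within_range": s.E1_within_range,
                }
                for i, s in enumerate(self.ranking)
            ]
        )


def relative_euclidean(E1: float, E2: float, target: ModuliTarget) -> float:
    """Euclidean norm of the relative errors against both targets."""
    return float(
        np.hypot(
            (E1 - target.E1_target) / target.E1_target,
            (E2 - target.E2_target) / target.E2_target,
        )
    )


def distance(
    E1: float,
    E2: float,
    target: ModuliTarget = ModuliTarget(),
    metric: Callable[[float, float, ModuliTarget], float] = relative_euclidean,
) -> float:
    """Distance of a mixture's moduli from the target; 0 iff exact match."""
    if E1 <= 0 or E2 <= 0:
        raise ValueError(f"moduli must be > 0, got E1={E1}, E2={E2}")
    return metric(E1, E2, target)


def rank_mixtures(
    estimates: Sequence[ModuliEstimate],
    target: ModuliTarget = ModuliTarget(),
    metric: Callable[[float, float, ModuliTarget], float] = relative_euclidean,
) -> ScreeningResult:
    """Rank mixtures by ascending distance; ties break on material, dilution."""
    if not estimates:
        raise ValueError("need at least one moduli estimate to rank")
    scores = [
        MixtureScore(
            material=e.material,
            dilution_pct=e.dilution_pct,
            E1=e.E1,
            E2=e.E2,
            distance=distance(e.E1, e.E2, target, metric),
            E1_within_range=target.E1_range[0] <= e.E1 <= target.E1_range[1],
        )
        for e in estimates
    ]
    scores.sort(key=lambda s: (s.distance, s.material, s.dilution_pct))
    return ScreeningResult(ranking=scores, target=target)


# ---------------------------------------------------------------------------
# pipeline driver


def _load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PhantomechError(f"config {path} must be a mapping")
    return cfg


def _mixture_sets(cfg: dict, base_seed: int):
    """Yield ReplicateSets from config: on-disk directories or synthetic specs."""
    mixtures = cfg.get("mixtures", [])
    if not mixtures:
        raise PhantomechError("config lists no mixtures")
    for i, m in enumerate(mixtures):
        if "directory" in m:
            yield load_replicates(
                m["directory"],
                material=m["material"],
                dilution_pct=float(m["dilution_pct"]),
                units=m.get("units", "auto"),
            )
        elif "synthetic" in m:
            s = m["synthetic"]
            kind = s["kind"]
            if kind == "bilinear":
                truth = BilinearTruth(
                    E1=float(s["E1"]),
                    E2=float(s["E2"]),
                    heel_start=float(s.get("heel_start", 0.20)),
                    heel_end=float(s.get("heel_end", 0.40)),
                    heel=s.get("heel", "cubic"),
                )
            else:
                truth = BlatzParams(
                    alpha=float(s["alpha"]), gamma=float(s["gamma"])
                )
            spec = SyntheticSpec(
                kind=kind,
                truth=truth,
                strain_max=float(s.get("strain_max", 0.70)),
                n_points=int(s.get("n_points", 200)),
                noise_rel=float(s.get("noise_rel", 0.02)),
                noise_abs=float(s.get("noise_abs", 0.05)),
                n_replicates=int(s.get("n_replicates", 5)),
                truth_jitter=float(s.get("truth_jitter", 0.0)),
                seed=base_seed + 1000 * i,
                material=m["material"],
                dilution_pct=float(m["dilution_pct"]),
            )
            rset, _ = gen_replicate_set(spec)
            yield rset
        else:
            raise PhantomechError(
                f"mixture entry {i} needs either 'directory' or 'synthetic'"
            )


def run_pipeline(config_path: str | Path, seed: int | None = None) -> dict:
    """Execute load → preprocess → moduli → Blatz → screening from a config.

    Writes moduli/Blatz/ranking CSVs and per-parameter quantile TXT files
    under the configured output directory and returns the in-memory
    results.  Any stage error is re-raised annotated with the stage name
    and the mixture identity.
    """
    cfg = _load_config(config_path)
    base_seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out_dir = Path(cfg.get("output_dir", "phantomech_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    pre = PreprocessConfig(
        e1_coverage_strain=float(cfg.get("e1_coverage_strain", 0.35)),
        e1_fit_limit_strain=float(cfg.get("e1_fit_limit_strain", 0.33)),
    )
    psi0 = tuple(cfg.get("psi0", DEFAULT_PSI0))
    n_runs = int(cfg.get("n_runs", 10))
    n_boot = int(cfg.get("n_boot", 10))
    target = ModuliTarget(
        E1_target=float(cfg.get("target", {}).get("E1", 20.0)),
        E2_target=float(cfg.get("target", {}).get("E2", 500.0)),
        E1_range=tuple(cfg.get("target", {}).get("E1_range", (13.6, 25.8))),
    )

    estimates: list[ModuliEstimate] = []
    blatz_rows = []
    for rset in _mixture_sets(cfg, base_seed):
        label = f"{rset.material} {rset.dilution_pct:g}%"
        try:
            est = estimate_moduli(
                rset, pre, psi0=psi0, n_runs=n_runs, n_boot=n_boot,
                base_seed=base_seed,
            )
        except PhantomechError as exc:
            raise PhantomechError(f"moduli stage failed for {label}: {exc}") from exc
        estimates.append(est)
        logger.info("%s: E1=%.2f kPa, E2=%.2f kPa", label, est.E1, est.E2)
        try:
            _, summary = fit_blatz_replicates(rset)
        except PhantomechError as exc:
            raise PhantomechError(f"Blatz stage failed for {label}: {exc}") from exc
        blatz_rows.append(summary)
        qpath = out_dir / (
            f"quantiles_{rset.material}_{rset.dilution_pct:g}.txt"
        )
        with open(qpath, "w", encoding="utf-8") as fh:
            fh.write("parameter\tquantile\tvalue\n")
            for name, qs in (
                ("alpha", summary.alpha_quantiles),
                ("gamma", summary.gamma_quantiles),
            ):
                for q, v in sorted(qs.items()):
                    fh.write(f"{name}\t{q:g}\t{v:.6g}\n")

    moduli_df = pd.DataFrame(
        {
            "material": [e.material for e in estimates],
            "dilution_pct": [e.dilution_pct for e in estimates],
            "E1_kPa": [round(e.E1, 6) for e in estimates],
            "E2_kPa": [round(e.E2, 6) for e in estimates],
            "psi1": [round(float(e.psi_mean[0]), 6) for e in estimates],
            "psi2": [round(float(e.psi_mean[1]), 6) for e in estimates],
            "psi3": [round(float(e.psi_mean[2]), 6) for e in estimates],
            "psi1_se": [round(float(e.psi_se[0]), 8) for e in estimates],
            "psi2_se": [round(float(e.psi_se[1]), 8) for e in estimates],
            "psi3_se": [round(float(e.psi_se[2]), 8) for e in estimates],
            "r2": [round(e.r2, 6) for e in estimates],
        }
    )
    moduli_df.to_csv(out_dir / "moduli.csv", index=False)

    blatz_df = pd.DataFrame(
        {
            "material": [s.material for s in blatz_rows],
            "dilution_pct": [s.dilution_pct for s in blatz_rows],
            "alpha_mean": [round(s.alpha_mean, 6) for s in blatz_rows],
            "alpha_sd": [round(s.alpha_sd, 6) for s in blatz_rows],
            "gamma_mean": [round(s.gamma_mean, 6) for s in blatz_rows],
            "gamma_sd": [round(s.gamma_sd, 6) for s in blatz_rows],
            "n_replicates": [s.n_replicates for s in blatz_rows],
        }
    )
    blatz_df.to_csv(out_dir / "blatz.csv", index=False)

    screening = rank_mixtures(estimates, target)
    screening.to_frame().to_csv(out_dir / "ranking.csv", index=False)
    logger.info(
        "closest mixture: %s at %g%% (distance %.4f)",
        screening.best.material,
        screening.best.dilution_pct,
        screening.best.distance,
    )
    return {
        "estimates": estimates,
        "blatz": blatz_rows,
        "screening": screening,
        "output_dir": out_dir,
    }
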