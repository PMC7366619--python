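"""Reading and writing uniaxial-compression stress-strain records.

Records are two-column plain text (strain, stress) separated by whitespace
or a comma, with an optional single header line.  The canonical in-memory
representation stores strain as a dimensionless fraction and stress as a
positive magnitude in kPa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .errors import (
    CurveParseError,
    InsufficientDataError,
    ReplicateLoadError,
    UnloadSegmentError,
)

MIN_POINTS = 4

Dialect = Literal["txt2col", "csv"]
Units = Literal["percent", "fraction", "auto"]

#: strain values above this are interpreted as percent when units="auto"
_PERCENT_THRESHOLD = 1.5

_FILENAME_RE = re.compile(
    r"^(?P<material>.+)_(?P<dilution>\d+(?:\.\d+)?)_(?P<replicate>[^_]+)$"
)


@dataclass
class StressStrainCurve:
    """One replicate's uniaxial-compression record.

    Attributes
    ----------
    strain : ndarray
        Nominal compressive strain, dimensionless fraction in ``[0, 1)``,
        strictly increasing.
    stress : ndarray
        Nominal compressive stress magnitude in kPa, ``>= 0``, aligned
        with ``strain``.
    material : str
        Material label, e.g. ``"ECOFLEX-0010"``.
    dilution_pct : float
        Thinner percentage (0-75).
    replicate_id : str
        Replicate label.
    strain_rate : float
        Crosshead speed in mm/min (default 5).
    """

    strain: np.ndarray
    stress: np.ndarray
    material: str = ""
    dilution_pct: float = 0.0
    replicate_id: str = ""
    strain_rate: float = 5.0

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.ndim != 1 or self.stress.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays")
        if self.strain.size != self.stress.size:
            raise ValueError("strain and stress must have equal length")
        if self.strain.size < MIN_POINTS:
            raise InsufficientDataError(
                f"curve needs >= {MIN_POINTS} points, got {self.strain.size}"
            )
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress))):
            raise ValueError("strain and stress must be finite")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if np.any(self.strain < 0) or np.any(self.strain >= 1):
            raise ValueError("strain fractions must lie in [0, 1)")
        if np.any(self.stress < 0):
            raise ValueError("stress magnitudes must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.strain.size)

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1])

    def truncated(self, max_strain: float) -> "StressStrainCurve":
        """Return a copy keeping only points with strain <= ``max_strain``."""
        keep = self.strain <= max_strain + 1e-12
        if int(keep.sum()) < MIN_POINTS:
            raise InsufficientDataError(
                f"truncation at {max_strain} leaves {int(keep.sum())} points "
                f"(< {MIN_POINTS}) for replicate {self.replicate_id!r}"
            )
        return replace(self, strain=self.strain[keep], stress=self.stress[keep])


@dataclass
class ReplicateSet:
    """All technical replicates for one silicone mixture."""

    material: str
    dilution_pct: float
    curves: list[StressStrainCurve] = field(default_factory=list)
    #: common truncation cutoff applied by preprocessing, if any
    cutoff: float | None = None
    #: False when the common cutoff fell below the coverage requirement
    coverage_ok: bool = True
    #: upper strain bound for the standalone low-strain linear window
    e1_window: float | None = None

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("ReplicateSet requires at least one curve")
        for c in self.curves:
            if c.material != self.material or c.dilution_pct != self.dilution_pct:
                raise ValueError(
                    f"curve {c.replicate_id!r} metadata ({c.material}, "
                    f"{c.dilution_pct}) does not match set "
                    f"({self.material}, {self.dilution_pct})"
                )
        ids = [c.replicate_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise ValueError(f"replicate_ids must be unique, got {ids}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self) -> Iterator[StressStrainCurve]:
        return iter(self.curves)


def _parse_row(raw: str, line_number: int) -> tuple[float, float] | None:
    """Parse one data row; return None for blank/comment lines."""
    stripped = raw.strip()
    if not stripped or stripped.startswith("#"):
        return None
    fields = [f for f in re.split(r"[,\s]+", stripped) if f]
    if len(fields) != 2:
        raise CurveParseError(
            f"expected 2 columns, found {len(fields)}: {raw.rstrip()!r}",
            line_number,
        )
    try:
        return float(fields[0]), float(fields[1])
    except ValueError:
        raise CurveParseError(
            f"non-numeric value in row: {raw.rstrip()!r}", line_number
        ) from None


def _is_header(raw: str) -> bool:
    fields = [f for f in re.split(r"[,\s]+", raw.strip()) if f]
    if len(fields) != 2:
        return True
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def parse_filename_metadata(path: str | Path) -> dict | None:
    """Extract (material, dilution_pct, replicate_id) from a filename.

    Expects the pattern ``<material>_<dilution>_<replicate>.<ext>``; the
    material label may itself contain underscores.  Returns None when the
    stem does not match.
    """
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        return None
    return {
        "material": m.group("material"),
        "dilution_pct": float(m.group("dilution")),
        "replicate_id": m.group("replicate"),
    }


def read_curve(
    path: str | Path,
    dialect: Dialect = "txt2col",
    units: Units = "auto",
    **metadata,
) -> StressStrainCurve:
    """Read one stress-strain record from a two-column text or CSV file.

    The curve is canonicalized: sorted by strain, exact-duplicate strain
    rows collapsed by averaging stress, and strain normalized to a
    fraction.  Metadata not supplied via keyword arguments is recovered
    from the ``<material>_<dilution>_<replicate>.<ext>`` filename pattern
    when it applies.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"txt2col", "csv"}
        Accepted for symmetry with :func:`write_curve`; parsing treats any
        run of whitespace or a comma as the delimiter either way.
    units : {"percent", "fraction", "auto"}
        Strain units stored in the file.  With ``"auto"`` the file is
        treated as percent when the maximum strain value exceeds 1.5.

    Raises
    ------
    CurveParseError
        Malformed row (message names the line number).
    InsufficientDataError
        Fewer than 4 data rows.
    UnloadSegmentError
        Strain decreases in file order (unload segment); truncate the file
        at peak strain before loading.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    for i, raw in enumerate(lines):
        if raw.strip():
            if _is_header(raw):
                start = i + 1
            break
    for line_number, raw in enumerate(lines[start:], start=start + 1):
        parsed = _parse_row(raw, line_number)
        if parsed is not None:
            rows.append(parsed)
    if len(rows) < MIN_POINTS:
        raise InsufficientDataError(
            f"{path}: found {len(rows)} data rows, need >= {MIN_POINTS}"
        )

    strain = np.array([r[0] for r in rows])
    stress = np.array([r[1] for r in rows])

    if units == "auto":
        units = "percent" if np.nanmax(strain) > _PERCENT_THRESHOLD else "fraction"
    if units == "percent":
        strain = strain / 100.0

    # unload detection happens in file order, before sorting
    diffs = np.diff(strain)
    if np.any(diffs < 0):
        first = int(np.argmax(diffs < 0)) + 1
        raise UnloadSegmentError(
            f"{path}: strain decreases at data row {first + 1} — the record "
            "contains an unload segment; truncate the file at peak strain"
        )

    # collapse exact-duplicate strain values by averaging their stresses
    order = np.argsort(strain, kind="stable")
    strain, stress = strain[order], stress[order]
    uniq, inverse, counts = np.unique(strain, return_inverse=True, return_counts=True)
    if uniq.size < strain.size:
        sums = np.zeros_like(uniq)
        np.add.at(sums, inverse, stress)
        stress = sums / counts
        strain = uniq

    meta = parse_filename_metadata(path) or {}
    meta.update({k: v for k, v in metadata.items() if v is not None})
    try:
        return StressStrainCurve(strain=strain, stress=stress, **meta)
    except (ValueError, InsufficientDataError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_curve(
    curve: StressStrainCurve,
    path: str | Path,
    dialect: Dialect = "txt2col",
    units: Units = "fraction",
) -> None:
    """Write a curve to disk, creating parent directories as needed.

    Values are written with 10 significant digits so that a write/read
    round trip reproduces the curve well beyond 6 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    strain = curve.strain * 100.0 if units == "percent" else curve.strain
    sep = "," if dialect == "csv" else " "
    lines = [f"strain{sep}stress"]
    for e, s in zip(strain, curve.stress):
        lines.append(f"{e:.10g}{sep}{s:.10g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_replicates(
    directory: str | Path,
    material: str,
    dilution_pct: float,
    dialect: Dialect = "txt2col",
    units: Units = "auto",
) -> ReplicateSet:
    """Load every replicate file for one mixture from a directory.

    Files must follow the ``<material>_<dilution>_<replicate>.<ext>``
    naming pattern; matches are loaded in lexicographic order.
    """
    directory = Path(directory)
    dil = f"{dilution_pct:g}"
    pattern = f"{material}_{dil}_*"
    paths = sorted(
        p for p in directory.glob(pattern) if p.is_file() and p.suffix != ".meta"
    )
    if not paths:
        raise ReplicateLoadError(
            f"no files matching {pattern!r} in {directory}"
        )
    curves, failures = [], []
    for p in paths:
        try:
            curves.append(read_curve(p, dialect=dialect, units=units))
        except Exception as exc:  # aggregate all offending files
            failures.append(f"{p.name}: {exc}")
    if failures:
        raise ReplicateLoadError(
            "replicate file(s) failed validation:\n  " + "\n  ".join(failures)
        )
    return ReplicateSet(material=material, dilution_pct=dilution_pct, curves=curves)
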