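"""Acquisition grids, relaxation surfaces and relaxation fingerprints.

A *relaxation surface* ``f(tau1, n)`` holds the normalized intensities of the
composite CPMG / T1-modulation experiment on a fixed two-dimensional
acquisition grid: the echo half-spacing ``tau1`` (first dimension) and the
echo-loop count ``n`` (second dimension), at a fixed T1-modulation delay
``tau2``.  A *fingerprint* is the cell-wise difference between a sample's
surface and a reference surface built from the six oil species,

    F(tau1, n) = f(tau1, n) - f_ref(tau1, n),

which removes the relaxation behaviour common to all vegetable oils and
leaves the species-specific residual pattern.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, GridMismatchError, ParseError

__all__ = [
    "AcquisitionGrid",
    "RelaxationSurface",
    "ReferenceSurface",
    "Fingerprint",
    "normalize_surface",
    "build_reference",
    "compute_fingerprint",
    "write_surface",
    "read_surface",
    "write_heatmap",
]

# Stable text format: 17 significant digits round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


def _check_schedule(values, name: str) -> tuple:
    vals = tuple(values)
    if len(vals) == 0:
        raise DomainError(f"{name} must be non-empty")
    arr = np.asarray(vals, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} entries must be positive and finite")
    if np.any(np.diff(arr) <= 0):
        raise DomainError(f"{name} must be strictly increasing (no duplicates)")
    return vals


@dataclass(frozen=True)
class AcquisitionGrid:
    """The (tau1, n) acquisition grid; tau1 in seconds, n an echo-loop count.

    Grid identity (exact float equality after unit conversion) is required
    for any surface arithmetic; there is no interpolation between grids.
    """

    tau1_schedule: tuple[float, ...]
    n_schedule: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "tau1_schedule", _check_schedule(self.tau1_schedule, "tau1_schedule")
        )
        n = _check_schedule(self.n_schedule, "n_schedule")
        if any(int(v) != v for v in n):
            raise DomainError("n_schedule entries must be integers")
        object.__setattr__(self, "n_schedule", tuple(int(v) for v in n))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.tau1_schedule), len(self.n_schedule))

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]


def _check_values(values, grid: AcquisitionGrid) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise GridMismatchError(
            f"values shape {arr.shape} does not match grid shape {grid.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise DomainError("surface values must be finite")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class RelaxationSurface:
    """Normalized intensities f(tau1, n), indexed (tau1-index, n-index)."""

    grid: AcquisitionGrid
    values: np.ndarray
    label: str = ""
    tau2: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.values, self.grid))


@dataclass(frozen=True)
class ReferenceSurface:
    """The reference f_ref(tau1, n) built from several species surfaces."""

    grid: AcquisitionGrid
    values: np.ndarray
    mode: str = "mean"
    source_labels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.values, self.grid))
        if self.mode not in ("mean", "smooth"):
            raise DomainError(f"unknown reference mode {self.mode!r}")

    @property
    def reference_id(self) -> str:
        return f"ref:{self.mode}:" + "+".join(self.source_labels)


@dataclass(frozen=True)
class Fingerprint:
    """The fingerprint F(tau1, n) = f - f_ref of one sample."""

    grid: AcquisitionGrid
    values: np.ndarray
    label: str = ""
    reference_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.values, self.grid))


def normalize_surface(
    raw_values: np.ndarray,
    single_pulse_intensity: float,
    grid: AcquisitionGrid,
    label: str = "",
    tau2: float = 0.0,
) -> RelaxationSurface:
    """Divide raw intensities by the single-pulse excitation intensity.

    The single-pulse experiment measures the total proton signal; dividing by
    it puts every surface on the common [0, 1] normalized-intensity scale.
    The divisor is recorded in the surface metadata.
    """
    if not np.isfinite(single_pulse_intensity) or single_pulse_intensity <= 0:
        raise DomainError(
            f"single_pulse_intensity must be positive, got {single_pulse_intensity}"
        )
    vals = np.asarray(raw_values, dtype=float) / single_pulse_intensity
    return RelaxationSurface(
        grid=grid,
        values=vals,
        label=label,
        tau2=tau2,
        meta={"single_pulse_intensity": float(single_pulse_intensity)},
    )


def _smooth_fit(grid: AcquisitionGrid, mean_vals: np.ndarray, order: tuple[int, int]) -> np.ndarray:
    # Separable polynomial in (log tau1, log n), evaluated back on the grid.
    # Logs are centred/scaled for conditioning; the fit is plain least squares.
    lt = np.log(np.asarray(grid.tau1_schedule))
    ln = np.log(np.asarray(grid.n_schedule, dtype=float))

    def _std(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    lt, ln = _std(lt), _std(ln)
    LT, LN = np.meshgrid(lt, ln, indexing="ij")
    cols = [
        (LT**p * LN**q).ravel()
        for p in range(order[0] + 1)
        for q in range(order[1] + 1)
    ]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, mean_vals.ravel(), rcond=None)
    return (A @ coef).reshape(grid.shape)


def build_reference(
    surfaces: list[RelaxationSurface],
    mode: str = "mean",
    order: tuple[int, int] = (3, 3),
) -> ReferenceSurface:
    """Build f_ref from >= 2 surfaces on identical grids.

    ``mode="mean"`` (default) is the cell-wise arithmetic mean of the input
    surfaces.  ``mode="smooth"`` additionally fits a separable low-order
    polynomial in (log tau1, log n) to that mean and evaluates it back on the
    grid, giving the curved-surface variant.
    """
    if len(surfaces) < 2:
        raise DomainError("a reference needs at least two source surfaces")
    grid = surfaces[0].grid
    for s in surfaces[1:]:
        if s.grid != grid:
            raise GridMismatchError(
                f"surface {s.label!r} grid differs from {surfaces[0].label!r}"
            )
    mean_vals = np.mean([s.values for s in surfaces], axis=0)
    if mode == "mean":
        vals = mean_vals
    elif mode == "smooth":
        vals = _smooth_fit(grid, mean_vals, order)
    else:
        raise DomainError(f"unknown reference mode {mode!r}")
    return ReferenceSurface(
        grid=grid,
        values=vals,
        mode=mode,
        source_labels=tuple(s.label for s in surfaces),
    )


def compute_fingerprint(
    surface: RelaxationSurface, reference: ReferenceSurface
) -> Fingerprint:
    """Cell-wise difference F = f - f_ref; grids must be identical."""
    if surface.grid != reference.grid:
        raise GridMismatchError(
            f"surface {surface.label!r} grid differs from the reference grid"
        )
    return Fingerprint(
        grid=surface.grid,
        values=surface.values - reference.values,
        label=surface.label,
        reference_id=reference.reference_id,
    )


# ---------------------------------------------------------------------------
# CSV round-trip (long format: tau1_s, n, intensity + "# key,value" metadata)
# ---------------------------------------------------------------------------

def _to_long_csv(grid: AcquisitionGrid, values: np.ndarray, meta: dict[str, str]) -> str:
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k},{v}\n")
    buf.write("tau1_s,n,intensity\n")
    for i, t1 in enumerate(grid.tau1_schedule):
        for j, n in enumerate(grid.n_schedule):
            buf.write(
                f"{_FLOAT_FMT % t1},{n},{_FLOAT_FMT % values[i, j]}\n"
            )
    return buf.getvalue()


def write_surface(obj: RelaxationSurface | Fingerprint, path) -> None:
    """Write a surface or fingerprint as long-format CSV (UTF-8, LF, '.' decimals)."""
    if isinstance(obj, Fingerprint):
        meta = {"kind": "fingerprint", "label": obj.label, "reference_id": obj.reference_id}
    elif isinstance(obj, ReferenceSurface):
        meta = {"kind": "reference", "label": obj.reference_id, "mode": obj.mode}
    else:
        meta = {"kind": "surface", "label": obj.label, "tau2_s": _FLOAT_FMT % obj.tau2}
    text = _to_long_csv(obj.grid, obj.values, meta)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def read_surface(path) -> RelaxationSurface | Fingerprint:
    """Read a long-format surface/fingerprint CSV written by :func:`write_surface`.

    The full grid must be present: a missing (tau1, n) cell is a parse error
    naming the cell.  Unknown extra columns are ignored with a warning.
    """
    meta: dict[str, str] = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#"):
                body = raw[1:].strip()
                if "," in body:
                    k, v = body.split(",", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(raw)
    try:
        df = pd.read_csv(io.StringIO("".join(lines)), float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    required = {"tau1_s", "n", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {sorted(extra)}")
    if df[list(required)].isna().any().any():
        bad = int(df[list(required)].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: missing value on data row {bad}")

    tau1s = tuple(sorted(df["tau1_s"].unique()))
    ns = tuple(int(v) for v in sorted(df["n"].unique()))
    grid = AcquisitionGrid(tau1s, ns)
    values = np.full(grid.shape, np.nan)
    ti = {t: i for i, t in enumerate(tau1s)}
    nj = {n: j for j, n in enumerate(ns)}
    for _, row in df.iterrows():
        values[ti[row["tau1_s"]], nj[int(row["n"])]] = row["intensity"]
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: grid cell (tau1={tau1s[i]}, n={ns[j]}) is missing"
        )
    if meta.get("kind") == "fingerprint":
        return Fingerprint(
            grid=grid,
            values=values,
            label=meta.get("label", ""),
            reference_id=meta.get("reference_id", ""),
        )
    return RelaxationSurface(
        grid=grid,
        values=values,
        label=meta.get("label", ""),
        tau2=float(meta.get("tau2_s", 0.0)),
        meta=meta,
    )


def write_heatmap(fingerprint: Fingerprint, path, image_path=None) -> None:
    """Write a fingerprint CSV and optionally render a (tau1, n) heat map."""
    write_surface(fingerprint, path)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(
            fingerprint.values,
            aspect="auto",
            origin="lower",
            cmap="RdBu_r",
            vmin=-np.abs(fingerprint.values).max(),
            vmax=np.abs(fingerprint.values).max(),
        )
        ax.set_xticks(range(len(fingerprint.grid.n_schedule)))
        ax.set_xticklabels(fingerprint.grid.n_schedule, fontsize=6, rotation=90)
        ax.set_yticks(range(len(fingerprint.grid.tau1_schedule)))
        ax.set_yticklabels(
            [f"{t * 1e6:.0f}" for t in fingerprint.grid.tau1_schedule], fontsize=6
        )
        ax.set_xlabel("echo loops n")
        ax.set_ylabel("tau1 (us)")
        ax.set_title(fingerprint.label)
        fig.colorbar(im, ax=ax, label="F(tau1, n)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
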