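"""Region features: reduce a fingerprint to eight region means and the 3D identifier.

The fingerprint grid is partitioned into eight rectangular regions labelled
A-H.  Each feature is the arithmetic mean of the fingerprint intensities in
its region (mean, not sum, so features are invariant to mask size).  The 3D
*identifier* of a sample is the (B, E, G) triple - the three regions found
most discriminative between oil species - and serves as the sample's
coordinates in the characteristic coordinate system used for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError, GridMismatchError, SchemaError
from .fingerprint import AcquisitionGrid, Fingerprint

__all__ = [
    "RegionSet",
    "FeatureVector",
    "Identifier",
    "REGION_LABELS",
    "default_regions",
    "extract_features",
    "identifier",
    "regions_to_json",
    "regions_from_json",
]

REGION_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass(frozen=True)
class RegionSet:
    """Disjoint cell masks over an acquisition grid, keyed by region label."""

    grid: AcquisitionGrid
    masks: dict[str, frozenset[tuple[int, int]]]

    def __post_init__(self):
        masks = {k: frozenset(tuple(c) for c in v) for k, v in self.masks.items()}
        object.__setattr__(self, "masks", masks)
        nt, nn = self.grid.shape
        seen: set[tuple[int, int]] = set()
        for label, cells in masks.items():
            if not cells:
                raise ConfigError(f"region {label!r} is empty")
            for i, j in cells:
                if not (0 <= i < nt and 0 <= j < nn):
                    raise ConfigError(f"region {label!r} cell {(i, j)} outside grid")
                if (i, j) in seen:
                    raise ConfigError(f"regions overlap at cell {(i, j)}")
                seen.add((i, j))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.masks))


@dataclass(frozen=True)
class FeatureVector:
    """Per-region mean fingerprint intensities for one sample."""

    label: str
    region_means: dict[str, float]


@dataclass(frozen=True)
class Identifier:
    """The (B, E, G) coordinates of a sample in identifier space."""

    b: float
    e: float
    g: float
    label: str = ""

    def __post_init__(self):
        if not all(np.isfinite([self.b, self.e, self.g])):
            raise DomainError("identifier coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.e, self.g])


def _bands(edges: list[int], size: int) -> list[range]:
    bounds = edges + [size]
    return [range(lo, hi) for lo, hi in zip([0] + edges, bounds)]


def default_regions(grid: AcquisitionGrid) -> RegionSet:
    """The default 2x4 rectangular tiling of the grid into regions A-H.

    tau1 is split into a low and a high band; n into four bands (on the
    default 18-point schedule the n splits fall at indices {4, 9, 14}).
    A-D sweep the n bands at low tau1, E-H at high tau1.  Any region
    geometry can be substituted via :func:`regions_from_json`.
    """
    nt, nn = grid.shape
    if nt < 2 or nn < 4:
        raise ConfigError(
            f"grid {grid.shape} too small to host 8 nonempty 2x4 regions"
        )
    tau1_bands = _bands([nt // 2], nt)
    n_bands = _bands([round(nn / 4.5), round(nn / 2), nn - round(nn / 4.5)], nn)
    masks = {}
    labels = iter(REGION_LABELS)
    for tb in tau1_bands:
        for nb in n_bands:
            masks[next(labels)] = frozenset((i, j) for i in tb for j in nb)
    return RegionSet(grid, masks)


def extract_features(fingerprint: Fingerprint, regions: RegionSet) -> FeatureVector:
    """Mean fingerprint intensity per region; extraction is linear in F."""
    if fingerprint.grid != regions.grid:
        raise GridMismatchError(
            f"fingerprint {fingerprint.label!r} grid differs from the region grid"
        )
    means = {
        label: float(np.mean([fingerprint.values[i, j] for i, j in sorted(cells)]))
        for label, cells in regions.masks.items()
    }
    return FeatureVector(label=fingerprint.label, region_means=means)


def identifier(features: FeatureVector) -> Identifier:
    """Select the (B, E, G) triple as the sample's 3D identifier."""
    missing = [k for k in ("B", "E", "G") if k not in features.region_means]
    if missing:
        raise SchemaError(
            f"feature vector {features.label!r} lacks region(s) {missing}"
        )
    rm = features.region_means
    return Identifier(b=rm["B"], e=rm["E"], g=rm["G"], label=features.label)


def regions_to_json(regions: RegionSet) -> str:
    """Serialize rectangular hulls of each region as inclusive index ranges."""
    out = {}
    for label, cells in regions.masks.items():
        ii = [i for i, _ in cells]
        jj = [j for _, j in cells]
        hull = {(i, j) for i in range(min(ii), max(ii) + 1) for j in range(min(jj), max(jj) + 1)}
        if hull != set(cells):
            raise ConfigError(f"region {label!r} is not rectangular; cannot serialize")
        out[label] = {"tau1_idx": [min(ii), max(ii)], "n_idx": [min(jj), max(jj)]}
    return json.dumps(out, indent=2, sort_keys=True)


def regions_from_json(text: str, grid: AcquisitionGrid) -> RegionSet:
    """Load a region set from JSON: {"A": {"tau1_idx": [lo,hi], "n_idx": [lo,hi]}, ...}."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"region JSON is malformed: {exc}") from exc
    masks = {}
    for label, ranges in raw.items():
        try:
            (ti_lo, ti_hi), (nj_lo, nj_hi) = ranges["tau1_idx"], ranges["n_idx"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"region {label!r} needs tau1_idx and n_idx ranges") from exc
        masks[label] = frozenset(
            (i, j) for i in range(ti_lo, ti_hi + 1) for j in range(nj_lo, nj_hi + 1)
        )
    return RegionSet(grid, masks)
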