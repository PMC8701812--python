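"""Forward signal model and synthetic study-panel generator.

The measurement being emulated is a composite low-field NMR pulse sequence:
a CPMG echo train (``n`` loops of echo half-spacing ``tau1``, so total
transverse evolution ``2 n tau1``) followed by a 90-degree pulse and a delay
``tau2`` that imprints longitudinal (T1) relaxation modulation.  For an oil
described as a discrete set of relaxation components (amplitude ``a_i``,
times ``T1_i``, ``T2_i``) the normalized signal is modelled as

    S(tau1, n, tau2) = sum_i a_i exp(-2 n tau1 / T2_i) exp(-tau2 / T1_i)
                       / sum_i a_i ,

i.e. mono-exponential transverse decay per component over the echo train and
a multiplicative T1 factor for the storage delay.  Pulse-level spin dynamics
(off-resonance, B1 inhomogeneity, diffusion) are out of scope.

The panel generator reproduces a realistic study design: six oil species
(FO, OL, SO, CO, PO, SFO) with several commercial brands each (28 specimens
in total), plus binary flaxseed-oil/soybean-oil mixtures at stated volume
ratios.  Brand-to-brand variation is modelled as multiplicative lognormal
jitter on every relaxation parameter; measurement noise is additive i.i.d.
Gaussian on the normalized intensity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    ConfigError,
    DomainError,
    FitFailureError,
    InvalidSampleError,
)
from .fingerprint import AcquisitionGrid, RelaxationSurface

__all__ = [
    "RelaxationComponent",
    "OilSample",
    "AcquisitionProtocol",
    "MixtureSeries",
    "PanelConfig",
    "PanelRecord",
    "Panel",
    "DEFAULT_SPECIES_LIBRARY",
    "DEFAULT_BRAND_COUNTS",
    "DEFAULT_TAU1_SCHEDULE",
    "DEFAULT_N_SCHEDULE",
    "DEFAULT_TAU2",
    "CALIBRATION_RATIOS",
    "VALIDATION_RATIOS",
    "simulate_signal",
    "simulate_surface",
    "make_brand",
    "mix",
    "simulate_classic_curves",
    "fit_monoexponential",
    "MonoExpFit",
    "generate_panel",
    "stage_rng",
]


@dataclass(frozen=True)
class RelaxationComponent:
    """One proton pool: relative amplitude plus T1/T2 time constants (seconds)."""

    amplitude: float
    t1: float
    t2: float

    def __post_init__(self):
        if not (self.amplitude >= 0):
            raise DomainError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (self.t1 > 0 and self.t2 > 0):
            raise DomainError("relaxation times must be positive")
        if self.t2 > self.t1:
            raise DomainError(
                f"t2 ({self.t2}) must not exceed t1 ({self.t1}); "
                "transverse relaxation is never slower than longitudinal"
            )


@dataclass(frozen=True)
class OilSample:
    """A specimen: a labelled, ordered set of relaxation components."""

    label: str
    components: tuple[RelaxationComponent, ...]
    provenance: str = "species"

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) == 0:
            raise InvalidSampleError(f"sample {self.label!r} has no components")
        if not (self.total_amplitude > 0):
            raise InvalidSampleError(f"sample {self.label!r} has zero total amplitude")

    @property
    def total_amplitude(self) -> float:
        return float(sum(c.amplitude for c in self.components))


# Acquisition schedules of the fingerprint experiment (seconds).
DEFAULT_TAU1_SCHEDULE: tuple[float, ...] = tuple(
    t * 1e-6 for t in (100, 150, 200, 250, 300, 400, 500)
)
DEFAULT_N_SCHEDULE: tuple[int, ...] = (
    3, 5, 10, 20, 40, 80, 100, 150, 200, 250, 300, 400, 500, 700, 900, 1200, 1500, 2500,
)
DEFAULT_TAU2: float = 0.100  # s


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Grid schedules, fixed tau2, noise level and RNG seed for one acquisition."""

    tau1_schedule: tuple[float, ...] = DEFAULT_TAU1_SCHEDULE
    n_schedule: tuple[int, ...] = DEFAULT_N_SCHEDULE
    tau2: float = DEFAULT_TAU2
    noise_sigma: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        # Grid construction validates monotone, duplicate-free schedules.
        grid = AcquisitionGrid(self.tau1_schedule, self.n_schedule)
        object.__setattr__(self, "tau1_schedule", grid.tau1_schedule)
        object.__setattr__(self, "n_schedule", grid.n_schedule)
        if not (self.tau2 >= 0):
            raise DomainError("tau2 must be nonnegative")
        if not (self.noise_sigma >= 0):
            raise DomainError("noise_sigma must be nonnegative")

    @property
    def grid(self) -> AcquisitionGrid:
        return AcquisitionGrid(self.tau1_schedule, self.n_schedule)


def _c(a: float, t1_ms: float, t2_ms: float) -> RelaxationComponent:
    return RelaxationComponent(a, t1_ms * 1e-3, t2_ms * 1e-3)


# Invented but physically plausible component sets for the six species:
# 2-3 proton pools each with T2 in [40, 200] ms and T1 in [120, 300] ms.
# T1 and T2 contrasts are deliberately decoupled across species (e.g. OL:
# short T2 / long T1; CO: long T2 / short T1) so the six (B, E, G)
# identifiers spread in all three dimensions instead of along a single
# fast-vs-slow axis, while mono-exponential fits stay similar.  Fully
# overridable via panel config.
DEFAULT_SPECIES_LIBRARY: dict[str, OilSample] = {
    "FO": OilSample("FO", (_c(0.60, 125, 45), _c(0.40, 170, 110)), "species"),
    "SO": OilSample("SO", (_c(0.55, 270, 100), _c(0.45, 300, 195)), "species"),
    "OL": OilSample("OL", (_c(0.60, 290, 55), _c(0.40, 300, 115)), "species"),
    "CO": OilSample("CO", (_c(0.45, 140, 110), _c(0.55, 175, 170)), "species"),
    "PO": OilSample(
        "PO", (_c(0.50, 150, 48), _c(0.20, 200, 110), _c(0.30, 280, 200)), "species"
    ),
    "SFO": OilSample("SFO", (_c(0.70, 230, 85), _c(0.30, 250, 140)), "species"),
}

# Study inventory: 28 commercial specimens.
DEFAULT_BRAND_COUNTS: dict[str, int] = {
    "SO": 4, "PO": 4, "CO": 5, "OL": 5, "FO": 5, "SFO": 5,
}

CALIBRATION_RATIOS: tuple[float, ...] = (0.10, 0.20, 0.30, 0.50, 0.70, 0.90)
VALIDATION_RATIOS: tuple[float, ...] = (0.20, 0.30, 0.40, 0.50, 0.70, 0.80)


@dataclass(frozen=True)
class MixtureSeries:
    """A binary adulteration series: base oil + adulterant at volume fractions."""

    base: str
    adulterant: str
    fractions: tuple[float, ...]
    tag: str = "calibration"

    def __post_init__(self):
        object.__setattr__(self, "fractions", tuple(float(v) for v in self.fractions))
        if any(not (0 <= v <= 1) for v in self.fractions):
            raise DomainError("mixture fractions must lie in [0, 1]")


def _default_mixture_series() -> tuple[MixtureSeries, ...]:
    return (
        MixtureSeries("FO", "SO", CALIBRATION_RATIOS, "calibration"),
        MixtureSeries("FO", "SO", VALIDATION_RATIOS, "validation"),
    )


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of the synthetic study panel."""

    species_library: dict[str, OilSample] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_LIBRARY)
    )
    brands_per_species: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BRAND_COUNTS)
    )
    brand_jitter_cv: float = 0.03
    mixture_series: tuple[MixtureSeries, ...] = field(
        default_factory=_default_mixture_series
    )
    seed: int = 0

    def __post_init__(self):
        if self.brand_jitter_cv < 0:
            raise DomainError("brand_jitter_cv must be nonnegative")
        for sp in self.brands_per_species:
            if sp not in self.species_library:
                raise ConfigError(f"brand count given for unknown species {sp!r}")
        for series in self.mixture_series:
            for sp in (series.base, series.adulterant):
                if sp not in self.species_library:
                    raise ConfigError(f"mixture series references unknown species {sp!r}")


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def simulate_signal(sample: OilSample, tau1: float, n: int, tau2: float) -> float:
    """Noiseless normalized intensity at one (tau1, n, tau2) grid point.

    Normalization divides by the single-pulse intensity ``sum_i a_i``, so the
    noiseless value lies in (0, 1] and equals 1 only with no decay at all.
    """
    if len(sample.components) == 0:  # pragma: no cover - blocked at construction
        raise InvalidSampleError("sample has no components")
    if not (tau1 > 0):
        raise DomainError(f"tau1 must be positive, got {tau1}")
    if n < 0 or int(n) != n:
        raise DomainError(f"n must be a nonnegative integer, got {n}")
    if tau2 < 0:
        raise DomainError(f"tau2 must be nonnegative, got {tau2}")
    a = np.array([c.amplitude for c in sample.components])
    t1 = np.array([c.t1 for c in sample.components])
    t2 = np.array([c.t2 for c in sample.components])
    s = np.sum(a * np.exp(-2.0 * n * tau1 / t2) * np.exp(-tau2 / t1))
    return float(s / np.sum(a))


def _surface_values(sample: OilSample, grid: AcquisitionGrid, tau2: float) -> np.ndarray:
    a = np.array([c.amplitude for c in sample.components])
    t1 = np.array([c.t1 for c in sample.components])
    t2 = np.array([c.t2 for c in sample.components])
    tt = np.asarray(grid.tau1_schedule)[:, None, None]  # (T, 1, 1)
    nn = np.asarray(grid.n_schedule, dtype=float)[None, :, None]  # (1, N, 1)
    decay = np.exp(-2.0 * nn * tt / t2[None, None, :]) * np.exp(-tau2 / t1)[None, None, :]
    return (decay * a[None, None, :]).sum(axis=2) / a.sum()


def simulate_surface(
    sample: OilSample,
    protocol: AcquisitionProtocol,
    rng: np.random.Generator | None = None,
) -> RelaxationSurface:
    """Simulate the full 2D acquisition for one sample.

    Additive zero-mean Gaussian noise of SD ``protocol.noise_sigma`` is drawn
    from ``rng`` (or from a generator seeded with ``protocol.seed`` if none is
    supplied), so identical seeds give identical surfaces.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    grid = protocol.grid
    vals = _surface_values(sample, grid, protocol.tau2)
    if protocol.noise_sigma > 0:
        vals = vals + rng.normal(0.0, protocol.noise_sigma, size=grid.shape)
    return RelaxationSurface(grid=grid, values=vals, label=sample.label, tau2=protocol.tau2)


def make_brand(
    species_template: OilSample,
    jitter_cv: float,
    seed: int | np.random.Generator,
    brand_label: str | None = None,
) -> OilSample:
    """Derive one commercial-brand realization from a species template.

    Every T1, T2 and amplitude is multiplied by an independent lognormal
    factor with unit median and coefficient of variation ``jitter_cv``
    (sigma = sqrt(log(1 + cv^2))).  The physical constraint t2 <= t1 is
    re-imposed by clipping t2 when the jitter violates it.
    """
    if jitter_cv < 0:
        raise DomainError("jitter_cv must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    label = brand_label or species_template.label
    if jitter_cv == 0:
        return replace(species_template, label=label, provenance="brand")
    sigma = np.sqrt(np.log1p(jitter_cv**2))
    comps = []
    for c in species_template.components:
        f_a, f_t1, f_t2 = np.exp(rng.normal(0.0, sigma, size=3))
        t1 = c.t1 * f_t1
        t2 = min(c.t2 * f_t2, t1)
        comps.append(RelaxationComponent(c.amplitude * f_a, t1, t2))
    return OilSample(label, tuple(comps), provenance="brand")


def mix(base: OilSample, adulterant: OilSample, v: float) -> OilSample:
    """Binary volume mixture: adulterant volume fraction ``v``.

    Equal proton density per unit volume is assumed, so the volume fraction
    equals the amplitude fraction: component lists are concatenated with base
    amplitudes scaled by (1 - v) and adulterant amplitudes by v.
    """
    if not (0 <= v <= 1):
        raise DomainError(f"volume fraction must lie in [0, 1], got {v}")
    # Scale each parent to unit total first so v is the *signal* fraction too.
    comps = [
        replace(c, amplitude=c.amplitude * (1 - v) / base.total_amplitude)
        for c in base.components
    ] + [
        replace(c, amplitude=c.amplitude * v / adulterant.total_amplitude)
        for c in adulterant.components
    ]
    comps = [c for c in comps if c.amplitude > 0] or [comps[0]]
    label = f"{base.label}+{adulterant.label}@v={v:.2f}"
    return OilSample(label, tuple(comps), provenance=f"mixture:{base.label}:{adulterant.label}:{v}")


def simulate_classic_curves(
    sample: OilSample, delays, kind: str
) -> np.ndarray:
    """Classical single-shot relaxometry curves (normalized).

    ``kind="IR"``:   inversion recovery, M(t) = sum a_i (1 - 2 exp(-t/T1_i)) / sum a_i
    ``kind="CPMG"``: echo-train decay,   M(t) = sum a_i exp(-t/T2_i) / sum a_i
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise DomainError("delays must be non-empty")
    if np.any(delays <= 0) or np.any(np.diff(delays) <= 0):
        raise DomainError("delays must be positive and strictly increasing")
    a = np.array([c.amplitude for c in sample.components])
    if kind == "IR":
        t1 = np.array([c.t1 for c in sample.components])
        m = (a[None, :] * (1 - 2 * np.exp(-delays[:, None] / t1[None, :]))).sum(axis=1)
    elif kind == "CPMG":
        t2 = np.array([c.t2 for c in sample.components])
        m = (a[None, :] * np.exp(-delays[:, None] / t2[None, :])).sum(axis=1)
    else:
        raise DomainError(f"kind must be 'IR' or 'CPMG', got {kind!r}")
    return m / a.sum()


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a single-component relaxation fit."""

    kind: str
    time_constant: float
    amplitude: float
    residual_rms: float


def fit_monoexponential(delays, values, kind: str) -> MonoExpFit:
    """Least-squares single-component fit of an IR or CPMG curve.

    CPMG model: ``A exp(-t/T)``; IR model: ``A (1 - 2 exp(-t/T))``.  On a
    noiseless single-component curve this recovers the generating time
    constant essentially exactly; on multi-component data it returns the
    usual effective (amplitude-weighted) time constant.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise DomainError("need at least 3 points for a mono-exponential fit")
    if kind == "CPMG":
        model = lambda tt, A, T: A * np.exp(-tt / T)
        pos = y > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            T0 = -1.0 / slope if slope < 0 else t[-1]
        else:  # pragma: no cover - pathological input
            T0 = t[t.size // 2]
        p0 = (max(y.max(), 1e-6), max(T0, t[0] / 10))
    elif kind == "IR":
        model = lambda tt, A, T: A * (1 - 2 * np.exp(-tt / T))
        # Null point of inversion recovery sits at t = T ln 2.
        i0 = int(np.argmin(np.abs(y)))
        p0 = (max(abs(y[-1]), 1e-6), max(t[i0] / np.log(2), t[0] / 10))
    else:
        raise DomainError(f"kind must be 'IR' or 'CPMG', got {kind!r}")
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000, xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise FitFailureError(
            f"{kind} mono-exponential fit failed to converge "
            f"(n={t.size}, p0={p0}): {exc}"
        ) from exc
    resid = y - model(t, *popt)
    return MonoExpFit(
        kind=kind,
        time_constant=float(popt[1]),
        amplitude=float(popt[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage RNG from a top-level seed and a stage name.

    The stage name is hashed (CRC32) into the seed sequence, so adding a new
    stage never perturbs the substreams consumed by existing stages.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode()),))
    )


@dataclass(frozen=True)
class PanelRecord:
    """One panel entry: the specimen, its measured surface, and design metadata."""

    sample: OilSample
    surface: RelaxationSurface
    species: str
    brand_index: int | None = None
    role: str = "pure"  # pure | calibration | validation
    ratio: float | None = None  # adulterant volume fraction for mixtures

    @property
    def label(self) -> str:
        return self.surface.label


@dataclass(frozen=True)
class Panel:
    """The full synthetic study: pure brands plus mixture series."""

    records: tuple[PanelRecord, ...]
    protocol: AcquisitionProtocol
    config: PanelConfig

    @property
    def pure(self) -> tuple[PanelRecord, ...]:
        return tuple(r for r in self.records if r.role == "pure")

    def mixtures(self, tag: str | None = None) -> tuple[PanelRecord, ...]:
        out = tuple(r for r in self.records if r.role != "pure")
        if tag is not None:
            out = tuple(r for r in out if r.role == tag)
        return out

    def by_label(self, label: str) -> PanelRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(label)


def generate_panel(
    config: PanelConfig, protocol: AcquisitionProtocol | None = None
) -> Panel:
    """Generate the full labelled panel of (sample, surface) pairs.

    One surface per brand per species, in deterministic species order, plus
    one surface per mixture-series fraction.  Mixtures are prepared from the
    first-brand realizations of their parent species (the same designated
    brands for every series, emulating a study that mixes two fixed
    commercial bottles).  All randomness (brand jitter, measurement noise)
    derives from ``config.seed`` via named substreams.
    """
    protocol = protocol or AcquisitionProtocol()
    jitter_rng = stage_rng(config.seed, "brand-jitter")
    noise_rng = stage_rng(config.seed, "measurement-noise")

    records: list[PanelRecord] = []
    first_brand: dict[str, OilSample] = {}
    for species in sorted(config.brands_per_species):
        template = config.species_library[species]
        for b in range(config.brands_per_species[species]):
            brand = make_brand(
                template, config.brand_jitter_cv, jitter_rng, f"{species}-b{b + 1}"
            )
            if b == 0:
                first_brand[species] = brand
            surf = simulate_surface(brand, protocol, noise_rng)
            records.append(
                PanelRecord(brand, surf, species=species, brand_index=b + 1, role="pure")
            )

    for series in config.mixture_series:
        for sp in (series.base, series.adulterant):
            if sp not in first_brand:
                base_tmpl = config.species_library[sp]
                first_brand[sp] = make_brand(
                    base_tmpl, config.brand_jitter_cv, jitter_rng, f"{sp}-b1"
                )
        for v in series.fractions:
            m = mix(first_brand[series.base], first_brand[series.adulterant], v)
            m = replace(
                m, label=f"{series.base}{series.adulterant}-{series.tag[:3]}-v{v:.2f}"
            )
            surf = simulate_surface(m, protocol, noise_rng)
            records.append(
                PanelRecord(
                    m,
                    surf,
                    species=f"{series.base}+{series.adulterant}",
                    role=series.tag,
                    ratio=v,
                )
            )
    return Panel(tuple(records), protocol, config)
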