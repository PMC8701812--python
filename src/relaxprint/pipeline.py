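"""End-to-end pipeline: simulate -> fingerprint -> featurize -> classify -> quantify.

:func:`analyze_panel` runs the whole analysis in memory and returns every
intermediate product; :func:`run_pipeline` wraps it with file IO, writing
surfaces, the reference, fingerprints, feature/classification/quantification
tables and a manifest of SHA-256 hashes so that identical configs and seeds
yield byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import features as feat
from . import fingerprint as fp
from . import forward_model as fm
from . import quantify as qt
from .config import RunConfig, load_run_config
from .errors import ConfigError
from .io import file_sha256, write_table

__all__ = [
    "AnalysisResult",
    "analyze_panel",
    "default_split",
    "panel_features",
    "quantification_study",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisResult:
    """Everything one pipeline run computes, in memory."""

    panel: fm.Panel
    reference: fp.ReferenceSurface
    fingerprints: dict[str, fp.Fingerprint]
    regions: feat.RegionSet
    features: pd.DataFrame  # index: label; columns A..H + species/role/ratio
    pca: chem.PCAModel
    scores: pd.DataFrame
    clusters: chem.ClusterModel
    classification: pd.DataFrame
    axis: chem.Axis | None
    quantification: qt.QuantificationReport | None


def default_split(
    features: pd.DataFrame,
    base: str = "FO",
    adulterant: str = "SO",
    n_cal_base: int = 4,
    n_cal_adulterant: int = 3,
    n_val_base: int = 1,
    n_val_adulterant: int = 1,
) -> qt.CalibrationSplit:
    """Build the study's calibration/validation split from the feature table.

    Calibration: the first ``n_cal_adulterant`` adulterant brands (ratio 1),
    the first ``n_cal_base`` base brands (ratio 0) and the calibration
    mixture series.  Validation: the next brands of each plus the validation
    mixtures.  Pure-brand order follows brand index, so the split is
    deterministic under a fixed panel seed.
    """
    region_cols = list(feat.REGION_LABELS)

    def _fv(label, row) -> feat.FeatureVector:
        return feat.FeatureVector(label, {r: float(row[r]) for r in region_cols})

    def _pures(species, start, count, ratio):
        rows = features[(features["species"] == species) & (features["role"] == "pure")]
        rows = rows.sort_index().iloc[start : start + count]
        if len(rows) < count:
            raise ConfigError(
                f"not enough pure {species} brands for the requested split"
            )
        return [(_fv(lbl, row), ratio) for lbl, row in rows.iterrows()]

    def _mixes(role):
        rows = features[features["role"] == role]
        return [(_fv(lbl, row), float(row["ratio"])) for lbl, row in rows.iterrows()]

    calibration = (
        _pures(adulterant, 0, n_cal_adulterant, 1.0)
        + _pures(base, 0, n_cal_base, 0.0)
        + _mixes("calibration")
    )
    validation = (
        _pures(adulterant, n_cal_adulterant, n_val_adulterant, 1.0)
        + _pures(base, n_cal_base, n_val_base, 0.0)
        + _mixes("validation")
    )
    return qt.CalibrationSplit(tuple(calibration), tuple(validation))


def panel_features(
    panel: fm.Panel,
    reference_mode: str = "mean",
    regions: feat.RegionSet | None = None,
) -> tuple[pd.DataFrame, fp.ReferenceSurface, dict[str, fp.Fingerprint], feat.RegionSet]:
    """Reference, fingerprints and the per-sample region-feature table.

    The reference surface is built once from the first brand of each species
    and frozen; the same reference serves mixtures and validation samples.
    """
    first_brands = [r.surface for r in panel.pure if r.brand_index == 1]
    if len(first_brands) < 2:
        raise ConfigError("need at least two species to build a reference")
    reference = fp.build_reference(first_brands, mode=reference_mode)
    fps = {
        r.label: fp.compute_fingerprint(r.surface, reference) for r in panel.records
    }
    regions = regions or feat.default_regions(panel.protocol.grid)
    rows = {}
    for r in panel.records:
        fv = feat.extract_features(fps[r.label], regions)
        rows[r.label] = {
            **{k: fv.region_means[k] for k in regions.labels},
            "species": r.species,
            "role": r.role,
            "ratio": np.nan if r.ratio is None else r.ratio,
        }
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "label"
    return features, reference, fps, regions


def quantification_study(
    seed: int = 0,
    noise_sigma: float = 1e-3,
    brand_jitter_cv: float = 0.0,
    split_kwargs: dict | None = None,
) -> qt.QuantificationReport:
    """The FO-SO adulteration quantification study in isolation.

    Runs the default panel at the given measurement-noise level and
    brand-variation level (jitter defaults to zero here: this entry point
    characterizes the calibration models' sensitivity to measurement noise
    alone) and fits the three univariate models plus PLS1 on the standard
    calibration/validation split.
    """
    protocol = fm.AcquisitionProtocol(noise_sigma=noise_sigma)
    cfg = fm.PanelConfig(brand_jitter_cv=brand_jitter_cv, seed=seed)
    panel = fm.generate_panel(cfg, protocol)
    features, *_ = panel_features(panel)
    return qt.run_quantification(default_split(features, **(split_kwargs or {})))


def analyze_panel(
    panel: fm.Panel,
    reference_mode: str = "mean",
    regions: feat.RegionSet | None = None,
    ellipsoid_level: float = 0.95,
    split_kwargs: dict | None = None,
) -> AnalysisResult:
    """Run the full fingerprint analysis of a simulated (or loaded) panel."""
    features, reference, fps, regions = panel_features(
        panel, reference_mode=reference_mode, regions=regions
    )
    pure = features[features["role"] == "pure"]
    region_cols = list(regions.labels)
    pca = chem.fit_pca(pure[region_cols])
    scores = chem.project(pca, pure[region_cols], k=min(3, len(region_cols)))

    ids_by_species: dict[str, list[feat.Identifier]] = {}
    all_ids: dict[str, feat.Identifier] = {}
    for label, row in features.iterrows():
        ident = feat.identifier(
            feat.FeatureVector(label, {r: float(row[r]) for r in region_cols})
        )
        all_ids[label] = ident
        if row["role"] == "pure":
            ids_by_species.setdefault(row["species"], []).append(ident)
    clusters = chem.fit_clusters(ids_by_species, level=ellipsoid_level)

    # Adulteration axis between the base and adulterant clusters of the
    # first mixture series, if any.
    axis = None
    series = panel.config.mixture_series
    if series:
        base, adulterant = series[0].base, series[0].adulterant
        axis = chem.adulteration_axis(
            clusters.ellipsoids[base], clusters.ellipsoids[adulterant]
        )

    cls_rows = []
    for label, ident in all_ids.items():
        res = chem.classify(ident, clusters)
        row = {
            "label": label,
            "species": features.loc[label, "species"],
            "role": features.loc[label, "role"],
            "predicted": res.predicted,
            **{f"m2_{sp}": res.mahalanobis2[sp] for sp in sorted(res.mahalanobis2)},
        }
        if axis is not None:
            t, off = chem.project_ratio(ident, axis)
            row["projected_ratio"] = t
            row["off_axis"] = off
        cls_rows.append(row)
    classification = pd.DataFrame(cls_rows).set_index("label")

    quantification = None
    if any(r.role == "calibration" for r in panel.records):
        quantification = qt.run_quantification(
            default_split(features, **(split_kwargs or {}))
        )

    return AnalysisResult(
        panel=panel,
        reference=reference,
        fingerprints=fps,
        regions=regions,
        features=features,
        pca=pca,
        scores=scores,
        clusters=clusters,
        classification=classification,
        axis=axis,
        quantification=quantification,
    )


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config, out_dir) -> dict:
    """Execute all stages per a validated run config, writing artifacts + manifest.

    Returns the manifest: per-stage parameters, artifact SHA-256 hashes and
    the seed, so reruns can be verified byte-for-byte.
    """
    cfg: RunConfig = load_run_config(config)
    out = Path(out_dir)
    (out / "surfaces").mkdir(parents=True, exist_ok=True)
    (out / "fingerprints").mkdir(exist_ok=True)

    protocol = cfg.protocol.to_protocol(seed=cfg.seed)
    panel_cfg = cfg.panel.to_panel_config(seed=cfg.seed)
    panel = fm.generate_panel(panel_cfg, protocol)

    regions = None
    if cfg.regions is not None:
        regions = feat.regions_from_json(json.dumps(cfg.regions), protocol.grid)

    result = analyze_panel(
        panel,
        reference_mode=cfg.reference_mode,
        regions=regions,
        ellipsoid_level=cfg.ellipsoid_level,
        split_kwargs=dict(
            base=cfg.split.base_species,
            adulterant=cfg.split.adulterant_species,
            n_cal_base=cfg.split.n_calibration_base,
            n_cal_adulterant=cfg.split.n_calibration_adulterant,
            n_val_base=cfg.split.n_validation_base,
            n_val_adulterant=cfg.split.n_validation_adulterant,
        ),
    )

    artifacts: dict[str, str] = {}

    def _record(path: Path):
        artifacts[str(path.relative_to(out))] = file_sha256(path)

    for rec in panel.records:
        p = out / "surfaces" / f"{rec.label}.csv"
        fp.write_surface(rec.surface, p)
        _record(p)
        q = out / "fingerprints" / f"{rec.label}.csv"
        fp.write_surface(result.fingerprints[rec.label], q)
        _record(q)

    ref_path = out / "reference.csv"
    fp.write_surface(result.reference, ref_path)
    _record(ref_path)
    ref_sidecar = out / "reference.json"
    ref_sidecar.write_text(
        json.dumps(
            {
                "schema_version": 1,
                "mode": result.reference.mode,
                "source_labels": list(result.reference.source_labels),
            },
            indent=2,
        )
        + "\n"
    )
    _record(ref_sidecar)

    regions_path = out / "regions.json"
    regions_path.write_text(feat.regions_to_json(result.regions) + "\n")
    _record(regions_path)

    features_path = out / "features.csv"
    write_table(result.features, features_path)
    _record(features_path)

    pca_path = out / "pca.json"
    pca_path.write_text(
        json.dumps(
            {
                "schema_version": 1,
                "columns": list(result.pca.columns),
                "column_means": _jsonable(result.pca.column_means),
                "column_scales": _jsonable(result.pca.column_scales),
                "loadings": _jsonable(result.pca.loadings),
                "explained_fraction": _jsonable(result.pca.explained_fraction),
            },
            indent=2,
        )
        + "\n"
    )
    _record(pca_path)

    clusters_path = out / "clusters.json"
    clusters_path.write_text(
        json.dumps(
            {
                "schema_version": 1,
                "level": cfg.ellipsoid_level,
                "clusters": {
                    sp: {
                        "center": _jsonable(e.center),
                        "covariance": _jsonable(e.covariance),
                        "radius2": e.radius2,
                    }
                    for sp, e in result.clusters.ellipsoids.items()
                },
            },
            indent=2,
        )
        + "\n"
    )
    _record(clusters_path)

    cls_path = out / "classification.csv"
    write_table(result.classification, cls_path)
    _record(cls_path)

    if result.quantification is not None:
        q = result.quantification
        models_path = out / "models.json"
        models_path.write_text(
            json.dumps(
                {
                    "schema_version": 1,
                    "univariate": {
                        r: {
                            "slope": m.slope,
                            "intercept": m.intercept,
                            "r2": m.r2,
                            "rmsec": m.rmsec,
                            "inv_slope": m.inv_slope,
                            "inv_intercept": m.inv_intercept,
                            "rmsep": q.univariate_metrics[r]["validation"].rmse,
                            "validation_slope": q.univariate_metrics[r]["validation"].slope,
                            "validation_intercept": q.univariate_metrics[r]["validation"].intercept,
                            "validation_r2": q.univariate_metrics[r]["validation"].r2,
                        }
                        for r, m in q.univariate.items()
                    },
                    "plsr": {
                        "n_factors": q.selected_factors,
                        "press_curve": _jsonable(q.press_curve),
                        "coef": _jsonable(q.plsr.coef),
                        "intercept": q.plsr.intercept,
                        "rmsec": q.plsr.rmsec,
                        "rmsep": q.plsr_metrics["validation"].rmse,
                        "validation_slope": q.plsr_metrics["validation"].slope,
                        "validation_r2": q.plsr_metrics["validation"].r2,
                    },
                },
                indent=2,
            )
            + "\n"
        )
        _record(models_path)
        pred_path = out / "predictions.csv"
        write_table(q.predictions, pred_path)
        _record(pred_path)

    manifest = {
        "schema_version": 1,
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "artifacts": dict(sorted(artifacts.items())),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
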