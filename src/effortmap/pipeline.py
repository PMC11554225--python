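"""End-to-end orchestration: files in, exposure products and metrics out.

The pipeline mirrors the production flow: ingest -> exclusion masking ->
trip linking -> 1-minute resampling -> window features -> observer labels
-> train (optionally tune) the forest -> predict fishing on all AIS trips
-> stepwise triage -> per-tier value distribution -> 500 m rasterization ->
raster combination -> lease summaries -> comparison metrics.  A manifest
with the seed and per-stage record counts is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, exposure, features, io, simulate, tracks
from .geometry import LocalMetricCRS
from .raster import GridSpec, read_ascii, write_ascii

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable).

    All paths are resolved relative to the config file's directory when
    loaded with :meth:`from_yaml`.
    """

    input_dir: str
    output_dir: str
    seed: int = 0
    grid_cell_m: float = 500.0
    footprint_sd_km: float = 5.0
    speed_cutoff_kn: float = 5.0
    tune: bool = False
    rfe: bool = False
    n_trees_grid: tuple = (100, 300)
    max_depth_grid: tuple = (10, None)
    cv_folds: int = 3
    holdout_fraction: float = 0.3
    use_depth: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(path))
        cfg = cls(**raw)
        for attr in ("input_dir", "output_dir"):
            p = getattr(cfg, attr)
            if not os.path.isabs(p):
                setattr(cfg, attr, os.path.join(base, p))
        cfg.n_trees_grid = tuple(cfg.n_trees_grid)
        cfg.max_depth_grid = tuple(
            None if d in (None, "null", "none") else int(d) for d in cfg.max_depth_grid
        )
        return cfg

    def validate(self):
        req = ["ais_tracks.csv", "trips.csv", "hauls_observed.csv", "vtr.csv",
               "leases.geojson", "moon.csv"]
        if self.use_depth:
            req.append("bathymetry.asc")
        missing = [f for f in req if not os.path.exists(os.path.join(self.input_dir, f))]
        if missing:
            raise ValueError(f"missing required inputs in {self.input_dir}: {missing}")


def _grouped_holdout(trip_ids, fraction, seed):
    """Deterministic grouped split: whole trips go to train or test."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(set(trip_ids)))
    rng.shuffle(ids)
    n_test = max(int(round(fraction * len(ids))), 1)
    return set(ids[n_test:]), set(ids[:n_test])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline from an input directory; returns the manifest."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    d = cfg.input_dir
    manifest = {"version": __version__, "seed": cfg.seed, "stages": {}}

    # ---- ingest -------------------------------------------------------
    ais, ais_report = io.read_tracks(os.path.join(d, "ais_tracks.csv"), source="AIS")
    vms_path = os.path.join(d, "vms_tracks.csv")
    vms, _ = (
        io.read_tracks(vms_path, source="VMS") if os.path.exists(vms_path) else (None, None)
    )
    trips = io.read_trips(os.path.join(d, "trips.csv"))
    hauls = io.read_hauls(os.path.join(d, "hauls_observed.csv"))
    vtr = io.read_vtr(os.path.join(d, "vtr.csv"))
    leases = io.read_polygons(os.path.join(d, "leases.geojson"))
    moon = io.read_moon(os.path.join(d, "moon.csv"))
    bathy = read_ascii(os.path.join(d, "bathymetry.asc")) if cfg.use_depth else None
    excl_path = os.path.join(d, "exclusion.geojson")
    exclusion = io.read_polygons(excl_path) if os.path.exists(excl_path) else {}
    manifest["stages"]["ingest"] = {
        "ais_pings": len(ais),
        "ais_rejected": ais_report.rejected,
        "vms_pings": 0 if vms is None else len(vms),
        "trips": len(trips),
        "observed_hauls": len(hauls),
        "vtr_reports": len(vtr),
        "leases": len(leases),
    }

    # ---- mask, link, resample ----------------------------------------
    if exclusion:
        ais = tracks.mask_exclusion_zone(ais, exclusion)
        if vms is not None:
            vms = tracks.mask_exclusion_zone(vms, exclusion)
    ais = tracks.link_trips(ais, trips)
    ais = ais[ais["trip_id"].notna()]
    if vms is not None:
        vms = tracks.link_trips(vms, trips)
        vms = vms[vms["trip_id"].notna()]
    resampled = tracks.resample_tracks(ais)
    manifest["stages"]["resample"] = {"ais_pings_1min": len(resampled)}

    # ---- study-area CRS and grid -------------------------------------
    lon0 = (resampled["lon"].min() + resampled["lon"].max()) / 2
    lat0 = (resampled["lat"].min() + resampled["lat"].max()) / 2
    crs = LocalMetricCRS(lat0, lon0)
    x, y = crs.to_xy(resampled["lat"].to_numpy(), resampled["lon"].to_numpy())
    pad = 8 * cfg.footprint_sd_km * 1000
    grid = GridSpec.from_bounds(
        x.min() - pad, y.min() - pad, x.max() + pad, y.max() + pad, cfg.grid_cell_m
    )

    # ---- features and labels -----------------------------------------
    feats = features.build_feature_table(resampled, bathymetry=bathy, moon=moon)
    observed_trips = sorted(set(hauls["trip_id"]) & set(feats["trip_id"].dropna()))
    labeled = feats[feats["trip_id"].isin(observed_trips) & feats["valid"]].copy()
    labeled["fishing"] = features.label_fishing(
        labeled, hauls[hauls["trip_id"].isin(observed_trips)]
    ).to_numpy()
    manifest["stages"]["features"] = {
        "feature_rows": len(feats),
        "labeled_rows": len(labeled),
        "observed_ais_trips": len(observed_trips),
    }

    # ---- train / tune / evaluate -------------------------------------
    train_ids, test_ids = _grouped_holdout(
        labeled["trip_id"], cfg.holdout_fraction, cfg.seed
    )
    train_df = labeled[labeled["trip_id"].isin(train_ids)]
    test_df = labeled[labeled["trip_id"].isin(test_ids)]

    feature_names = list(features.FEATURE_NAMES)
    fc = classify.ForestConfig(seed=cfg.seed)
    if cfg.tune:
        fc = classify.tune(
            train_df, train_df["fishing"], train_df["trip_id"],
            n_trees_grid=cfg.n_trees_grid, max_depth_grid=cfg.max_depth_grid,
            cv_folds=cfg.cv_folds, base=fc, feature_names=feature_names,
        )
    if cfg.rfe:
        feature_names, _ = classify.select_features(
            train_df, train_df["fishing"], train_df["trip_id"],
            config=fc, candidates=feature_names, cv_folds=cfg.cv_folds,
        )
    model = classify.train(train_df, train_df["fishing"], fc,
                           feature_names=feature_names)
    test_pred, _ = classify.predict(model, test_df)
    metrics = classify.evaluate(test_pred, test_df["fishing"])
    cutoff_acc = evaluate.cutoff_accuracy(
        test_df["sog"], test_df["fishing"], cfg.speed_cutoff_kn
    )
    classify.save_model(model, os.path.join(cfg.output_dir, "model.joblib"))
    manifest["stages"]["model"] = {
        "config": dataclasses.asdict(model.config),
        "features": model.selected_features,
        "oob_error": round(model.oob_error, 6),
        "holdout": metrics.as_dict(),
        "holdout_speed_cutoff_accuracy": round(cutoff_acc, 6),
    }

    # ---- predict fishing on all AIS trips ----------------------------
    pred_df = feats[feats["valid"]].copy()
    pred_labels, _ = classify.predict(model, pred_df)
    pred_df["fishing"] = pred_labels
    ais_fishing = pred_df[pred_df["fishing"]][["trip_id", "lat", "lon"]]
    manifest["stages"]["predict"] = {
        "pings_classified": len(pred_df),
        "fishing_pings": int(pred_labels.sum()),
    }

    # ---- triage and exposure -----------------------------------------
    availability = trips[["trip_id"]].copy()
    availability["has_ais"] = trips["trip_id"].isin(set(ais["trip_id"].dropna()))
    availability["has_vms"] = (
        trips["trip_id"].isin(set(vms["trip_id"].dropna())) if vms is not None else False
    )
    availability["has_vtr"] = trips["trip_id"].isin(set(vtr["trip_id"]))
    tiers, coverage = exposure.triage(availability)

    fp_lookup = vtr.set_index("trip_id")

    def footprint(trip_id):
        if trip_id not in fp_lookup.index:
            return None
        row = fp_lookup.loc[trip_id]
        return simulate.gaussian_footprint(
            grid, crs, row["reported_lat"], row["reported_lon"], cfg.footprint_sd_km
        )

    result = exposure.build_exposure(
        trips, tiers, ais_fishing, vms, footprint, grid, crs,
        speed_cutoff_kn=cfg.speed_cutoff_kn,
    )
    lease_table = exposure.lease_exposure({"usd": result.combined}, leases, crs)
    write_ascii(result.combined, os.path.join(cfg.output_dir, "exposure_combined.asc"))
    write_ascii(result.by_tier["points"], os.path.join(cfg.output_dir, "exposure_points.asc"))
    write_ascii(result.by_tier["VTR"], os.path.join(cfg.output_dir, "exposure_vtr.asc"))
    lease_table.to_csv(os.path.join(cfg.output_dir, "lease_exposure.csv"), index=False)
    result.coverage.to_csv(os.path.join(cfg.output_dir, "coverage.csv"), index=False)

    total_landed = float(trips["landed_value"].sum())
    total_raster = result.combined.total()
    manifest["stages"]["exposure"] = {
        "coverage": result.coverage.to_dict(orient="records"),
        "demoted_trips": len(result.demoted),
        "points_outside_grid": result.n_outside,
        "total_landed_value": round(total_landed, 2),
        "total_raster_value": round(total_raster, 2),
        "conservation_rel_error": abs(total_raster - total_landed)
        / max(total_landed, 1e-12),
    }

    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    digest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["manifest_sha256"] = digest
    return manifest
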