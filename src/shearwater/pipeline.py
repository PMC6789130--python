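"""Reproducible simulate -> geolocate -> phenology -> kde -> assign pipeline.

Each stage reads/writes plain CSV/JSON under ``out_dir`` and is recorded in
a run manifest (derived seeds, record counts, SHA-256 of every output), so
a run is fully reproducible from its config.  Stages are thin orchestration
over the library modules; any of them can be re-run from the interchange
files alone.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, geoloc, io, isotopes, phenology, spaceuse, synth

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_fixtures",
    "fixture_filter_track",
    "fixture_ward_points",
    "fixture_ellipse_points",
]


@dataclass
class ColonyConfig:
    population: str
    n_birds: int = 2
    year: int = 2012
    n_isotope_birds: int = 40


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    colonies: list = field(default_factory=lambda: [ColonyConfig("Menorca")])
    stages: tuple = ("simulate", "geolocate", "phenology", "kde", "isotopes")
    # stage parameters
    threshold: float = 10.0
    ea: str | float = "auto"
    vmax_kmh: float = 55.0
    exodus_min_days: int = 5
    min_migration_days: int = 30
    kde_levels: tuple = (25, 50, 70, 90)
    kde_cell_km: float = 10.0
    isotope_preset: str | None = None  # None -> fit on tracked birds
    feather: str = "P6"
    cadence_min: float = 2.0
    twilight_jitter_sd_min: float = 2.0
    shading_events_per_day: float = 0.2

    def __post_init__(self):
        self.colonies = [
            c if isinstance(c, ColonyConfig) else ColonyConfig(**c) for c in self.colonies
        ]
        for c in self.colonies:
            if c.population not in synth.COLONIES:
                raise ValueError(f"unknown population {c.population!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["kde_levels"] = list(self.kde_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "kde_levels" in d:
            d["kde_levels"] = tuple(d["kde_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest, stage, outputs: list[Path], counts: dict):
    manifest["stages"].append(
        {
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "counts": counts,
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    seq = np.random.SeedSequence(config.seed)
    sub = {name: s for name, s in zip(
        ("simulate", "geolocate", "phenology", "kde", "isotopes"), seq.spawn(5))}

    birds: list[dict] = []  # per-bird records shared across stages
    try:
        for stage in config.stages:
            if stage == "simulate":
                _stage_simulate(config, out, sub["simulate"], birds, manifest)
            elif stage == "geolocate":
                _stage_geolocate(config, out, birds, manifest)
            elif stage == "phenology":
                _stage_phenology(config, out, birds, manifest)
            elif stage == "kde":
                _stage_kde(config, out, birds, manifest)
            elif stage == "isotopes":
                _stage_isotopes(config, out, manifest)
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, out, seedseq, birds, manifest):
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    outputs, truth_rows = [], []
    for colony_cfg, cseq in zip(config.colonies, seedseq.spawn(len(config.colonies))):
        scheds = synth.simulate_cohort(
            colony_cfg.population, colony_cfg.n_birds, colony_cfg.year,
            int(cseq.generate_state(1)[0] % 2**31),
        )
        iso_seed = int(cseq.generate_state(2)[1] % 2**31)
        cohort = synth.simulate_isotope_cohort(
            colony_cfg.population, colony_cfg.n_isotope_birds, iso_seed,
            feather=config.feather, year=colony_cfg.year,
        )
        iso_path = d / f"isotopes_{colony_cfg.population}.csv"
        io.write_isotopes_csv(cohort, iso_path)
        outputs.append(iso_path)
        for i, sch in enumerate(scheds):
            light = synth.simulate_light(
                sch, cadence_min=config.cadence_min,
                twilight_jitter_sd_min=config.twilight_jitter_sd_min,
                shading_events_per_day=config.shading_events_per_day,
                seed=int(cseq.generate_state(3 + 2 * i)[-1] % 2**31),
            )
            imm = synth.simulate_immersion(
                sch, seed=int(cseq.generate_state(4 + 2 * i)[-1] % 2**31)
            )
            lp = d / f"light_{sch.bird_id}.csv"
            ip = d / f"immersion_{sch.bird_id}.csv"
            io.write_light_csv(light, lp)
            io.write_immersion_csv(imm, ip)
            outputs += [lp, ip]
            birds.append({"schedule": sch, "light": light, "immersion": imm,
                          "population": colony_cfg.population})
            truth_rows.append({
                "bird_id": sch.bird_id, "population": sch.population,
                "sex": sch.sex, "region": sch.region, **sch.truth,
            })
    tp = d / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(tp, index=False)
    outputs.append(tp)
    _record(manifest, "simulate", outputs,
            {"birds": len(birds), "colonies": len(config.colonies)})


def _stage_geolocate(config, out, birds, manifest):
    d = out / "geolocate"
    d.mkdir(exist_ok=True)
    all_fixes, cal_report = [], {}
    for b in birds:
        sch = b["schedule"]
        pairs = geoloc.detect_twilights(b["light"], config.threshold)
        if config.ea == "auto":
            window = (dt.date(sch.year, 4, 1), dt.date(sch.year, 4, 30))
            try:
                cal = geoloc.calibrate_ea(
                    {float(ea): geoloc.positions_from_twilights(pairs, float(ea))
                     for ea in geoloc.DEFAULT_EA_GRID},
                    (sch.colony_lon, sch.colony_lat), window,
                )
                ea = cal.ea
                cal_report[sch.bird_id] = {"ea": cal.ea, "score_km": cal.score_km}
            except ValueError as err:
                warnings.warn(f"{sch.bird_id}: calibration failed ({err}); EA=-3.5")
                ea = -3.5
        else:
            ea = float(config.ea)
        fixes = geoloc.positions_from_twilights(pairs, ea)
        fixes = geoloc.filter_track(fixes, vmax_kmh=config.vmax_kmh)
        fixes.insert(0, "bird_id", sch.bird_id)
        b["fixes"] = fixes
        all_fixes.append(fixes)
    fp = d / "fixes.csv"
    io.write_fixes_csv(pd.concat(all_fixes, ignore_index=True), fp)
    cp = d / "calibration.json"
    cp.write_text(json.dumps(cal_report, indent=1))
    n_all = sum(len(b["fixes"]) for b in birds)
    n_ret = sum(int(b["fixes"]["retained"].sum()) for b in birds)
    _record(manifest, "geolocate", [fp, cp],
            {"fixes": n_all, "retained": n_ret})


def _stage_phenology(config, out, birds, manifest):
    d = out / "phenology"
    d.mkdir(exist_ok=True)
    summaries = []
    for b in birds:
        sch = b["schedule"]
        s = phenology.summarize_bird(
            sch.bird_id, b["immersion"], b["light"],
            (sch.colony_lon, sch.colony_lat), sch.sex,
            exodus_min_days=config.exodus_min_days,
            min_migration_days=config.min_migration_days,
        )
        b["phenology"] = s
        summaries.append(s)
    # impute missing returns from same-population cohorts
    for b in birds:
        s = b["phenology"]
        if s.first_night_visit is None:
            cohort = [x["phenology"] for x in birds
                      if x["population"] == b["population"]]
            phenology.impute_return_date(cohort, s)
    rows = [
        {
            "bird_id": s.bird_id,
            "last_night_visit": s.last_night_visit,
            "first_night_visit": s.first_night_visit,
            "first_day_visit": s.first_day_visit,
            "laying_date": s.laying_date,
            "last_day_visit": s.last_day_visit,
            "imputed": ";".join(sorted(s.imputed)),
        }
        for s in summaries
    ]
    pp = d / "phenology.csv"
    pd.DataFrame(rows).to_csv(pp, index=False)
    _record(manifest, "phenology", [pp], {"birds": len(summaries)})


def _stage_kde(config, out, birds, manifest):
    d = out / "kde"
    d.mkdir(exist_ok=True)
    outputs = []
    counts = {}
    by_pop: dict[str, list] = {}
    for b in birds:
        s = b.get("phenology")
        fx = b["fixes"]
        fx = fx[fx["retained"]]
        if s is not None and s.last_night_visit and s.first_night_visit:
            fx = fx[(fx["date"] > s.last_night_visit) & (fx["date"] < s.first_night_visit)]
        if len(fx):
            by_pop.setdefault(b["population"], []).append(fx)
    for pop, frames in by_pop.items():
        # birds weighted equally in the pooled density
        xy, w = [], []
        for f in frames:
            pts = spaceuse.project(f)
            xy.append(pts.xy)
            w.append(np.full(pts.n, 1.0 / (len(frames) * pts.n)))
        allxy = np.vstack(xy)
        if len(allxy) < 10:
            warnings.warn(f"{pop}: too few non-breeding fixes for KDE")
            continue
        h = spaceuse.plugin_bandwidth(allxy)
        grid = spaceuse.kernel_density(
            allxy, h, cell_km=config.kde_cell_km, weights=np.concatenate(w)
        )
        cs = spaceuse.contour_levels(grid, config.kde_levels)
        ap = d / f"density_{pop}.asc"
        gp = d / f"contours_{pop}.geojson"
        spaceuse.write_esri_ascii(grid, ap)
        spaceuse.contours_to_geojson(cs, gp, params=spaceuse.LambertParams())
        outputs += [ap, gp]
        counts[pop] = int(len(allxy))
    _record(manifest, "kde", outputs, {"fixes_used": counts})


def _stage_isotopes(config, out, manifest):
    d = out / "isotopes"
    d.mkdir(exist_ok=True)
    frames = [
        io.read_isotopes_csv(p) for p in sorted((out / "simulate").glob("isotopes_*.csv"))
    ]
    allsamp = pd.concat(frames, ignore_index=True)
    if config.isotope_preset:
        model = isotopes.get_preset(config.isotope_preset)
        model_meta = {"preset": model.name}
    else:
        tracked = allsamp[allsamp["tracked"] & (allsamp["region"] != "")]
        model = isotopes.fit_lda(tracked)
        acc, _ = isotopes.loocv(tracked)
        model_meta = {
            "preset": None,
            "n_train": model.n_train,
            "wilks_lambda": model.wilks_lambda,
            "rao_f": model.rao_f,
            "bartlett_chi2": model.bartlett_chi2,
            "loocv_accuracy": acc,
            "canonical": model.canonical,
            "fisher": model.fisher,
        }
    rows = []
    for pop, sub in allsamp.groupby("population"):
        untracked = sub[~sub["tracked"]]
        res = isotopes.assign_untracked(model, untracked)
        if len(res["assignments"]):
            a = res["assignments"].copy()
            a.insert(1, "population", pop)
            rows.append(a)
        model_meta[f"proportions_{pop}"] = res["proportions"]
    ap = d / "assignments.csv"
    pd.concat(rows, ignore_index=True).to_csv(ap, index=False)
    mp = d / "model.json"
    mp.write_text(json.dumps(model_meta, indent=1, default=str))
    _record(manifest, "isotopes", [ap, mp],
            {"untracked_assigned": int(sum(len(r) for r in rows))})


# ---------------------------------------------------------------------------
# deterministic test fixtures


def fixture_filter_track(seed: int = 0) -> pd.DataFrame:
    """20 fixes with planted violations: 2 latitude, 1 speed, 3 equinox.

    Fixes are 12 h apart (two per day); the brute-force expectation is 14
    retained.
    """
    rows = []

    def add(iso_time, lon, lat):
        t = np.datetime64(iso_time, "s")
        rows.append({
            "date": t.astype("datetime64[D]").astype(dt.date),
            "time": t, "kind": "noon" if len(rows) % 2 == 0 else "midnight",
            "lon": lon, "lat": lat, "filters": "", "retained": True,
        })

    base = np.datetime64("2012-04-05T12:00:00", "s")
    lat_track = [40.0, 40.05, 40.1, 40.15, 40.2, 40.25]
    for i, la in enumerate(lat_track):  # rows 0-5: clean
        add(base + np.timedelta64(12 * i, "h"), 4.0 + 0.05 * i, la)
    add(base + np.timedelta64(72, "h"), 4.3, 47.5)    # row 6: 800 km in 12 h
    add(base + np.timedelta64(84, "h"), 4.35, 40.3)   # row 7: back on track
    add(base + np.timedelta64(96, "h"), 4.4, 55.0)    # row 8: lat > 52
    add(base + np.timedelta64(108, "h"), 4.45, 28.0)  # row 9: lat < 30
    for i in range(7):  # rows 10-16: clean
        add(base + np.timedelta64(120 + 12 * i, "h"), 4.5 + 0.05 * i, 40.35 + 0.05 * i)
    sept = np.datetime64("2012-09-20T12:00:00", "s")  # rows 17-19: equinox window
    for i in range(3):
        add(sept + np.timedelta64(12 * i, "h"), 4.0 + 0.05 * i, 40.0 + 0.05 * i)
    return pd.DataFrame(rows)


def fixture_ward_points(seed: int = 0) -> pd.DataFrame:
    """12 bivariate isotope points in two loose groups (for Ward oracles)."""
    rng = np.random.default_rng(seed)
    a = rng.normal([11.5, -17.5], [0.8, 0.5], size=(6, 2))
    b = rng.normal([14.2, -16.2], [0.8, 0.5], size=(6, 2))
    xy = np.vstack([a, b])
    return pd.DataFrame({"d15N": xy[:, 0], "d13C": xy[:, 1]})


def fixture_ellipse_points(seed: int = 0) -> pd.DataFrame:
    """8 bivariate isotope points (for SEA / hull oracles)."""
    rng = np.random.default_rng(seed + 1)
    xy = rng.normal([13.0, -17.0], [1.2, 0.6], size=(8, 2))
    return pd.DataFrame({"d15N": xy[:, 0], "d13C": xy[:, 1]})


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the deterministic fixture bundle; returns path -> sha256."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_fixes_csv(fixture_filter_track(seed), out / "filter_track_20fix.csv")
    fixture_ward_points(seed).to_csv(out / "ward_12point.csv", index=False)
    fixture_ellipse_points(seed).to_csv(out / "ellipse_8point.csv", index=False)
    sch = synth.simulate_schedule("Menorca", 2012, seed=seed)
    io.write_light_csv(
        synth.simulate_light(sch, cadence_min=10.0, seed=seed), out / "birdyear_light.csv"
    )
    io.write_immersion_csv(
        synth.simulate_immersion(sch, seed=seed), out / "birdyear_immersion.csv"
    )
    return {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
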