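"""End-to-end orchestration: landscape -> tracks -> ODBA -> iSSA -> behavior.

A single YAML config carries all paths and thresholds (the defaults are the
analysis defaults: accuracy < 10 m, speed <= 5 m/s, 10-min steps, depth
window [-0.5, 1] m, 10 available steps per stratum).  ``run_all`` executes
the stages, writes per-bird fit JSONs, an AICc table, RSS curves, corrected
step-length kernels, the ODBA mixed-model summary, and a machine-readable
run log with per-filter removal counts and the list of birds excluded for
separation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, issa, odba, tracks
from .grids import CLASS_NAMES, load_landscape_npz
from .landscape import read_tide_csv
from .synthetic import SITE_LAT, SITE_LON

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured run configuration; unknown keys are rejected."""

    tracks_csv: str = "tracks.csv"
    bursts_csv: str = ""
    landscape_npz: str = "landscape.npz"
    tide_csv: str = "tide.csv"
    out_dir: str = "out"

    site_lat: float = SITE_LAT
    site_lon: float = SITE_LON

    max_accuracy_m: float = 10.0
    max_speed_ms: float = 5.0
    min_solar_elevation_deg: float = 0.0
    interval_s: float = 600.0
    tolerance_s: float = 60.0
    depth_window: tuple[float, float] = (-0.5, 1.0)
    n_avail: int = 10
    burst_dialect: str = "packed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_accuracy_m <= 0 or self.max_speed_ms <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.interval_s <= 0 or self.tolerance_s < 0:
            raise ValueError("interval must be positive, tolerance non-negative")
        lo, hi = self.depth_window
        if not lo < hi:
            raise ValueError("depth window must satisfy lo < hi")
        if self.n_avail < 1:
            raise ValueError("n_avail must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "depth_window" in raw:
            raw["depth_window"] = tuple(raw["depth_window"])
        return cls(**raw)


def _bird_rng(master_seed: int, bird_id: str) -> np.random.Generator:
    """Child stream per bird, stable under reordering of birds."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, abs(hash_stable(bird_id))]))


def hash_stable(s: str) -> int:
    """Deterministic 31-bit hash of a string (Python's hash is salted)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


def prepare_bird_strata(
    observed: pd.DataFrame,
    habitat,
    elev,
    tide,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, issa.MovementKernel]:
    """One bird: tentative kernel, availability sample, covariates, window."""
    kernel = issa.fit_tentative_kernel(observed)
    strata = issa.sample_available(observed, kernel, config.n_avail, rng)
    strata = issa.attach_covariates(strata, habitat, elev, tide)
    strata = tracks.apply_depth_window(strata, *config.depth_window)
    return strata, kernel


def summarize_depth_density(
    steps: pd.DataFrame,
    lo: float = -0.5,
    hi: float = 1.0,
    n_bins: int = 30,
) -> pd.DataFrame:
    """Histogram densities of depth per wetland x case over the window.

    Densities integrate to 1 within each wetland x case group; classes with
    no members are omitted with a warning.
    """
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for wetland in CLASS_NAMES:
        for case in ("observed", "available"):
            sel = steps[(steps["wetland_end"].astype(str) == wetland)
                        & (steps["case"] == case)]
            if sel.empty:
                log.warning("depth density: no %s members in %s", case, wetland)
                continue
            dens, _ = np.histogram(sel["depth_end"], bins=edges, density=True)
            rows += [(wetland, case, m, d) for m, d in zip(mids, dens)]
    return pd.DataFrame(rows, columns=["wetland", "case", "depth", "density"])


def steps_by_end_wetland(strata: pd.DataFrame) -> pd.Series:
    """Observed-step counts by end wetland (track-summary table layout)."""
    obs = strata[strata["case"] == "observed"]
    counts = obs["wetland_end"].astype(str).value_counts()
    return counts.reindex(list(CLASS_NAMES), fill_value=0)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"filters": {}, "birds": {}, "excluded_birds": []}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("landscape")
        habitat, elev = load_landscape_npz(config.landscape_npz)
        tide = read_tide_csv(config.tide_csv)
    except Exception as e:
        raise RuntimeError(f"landscape stage failed: {e}") from e

    try:
        stage("tracks")
        fixes = tracks.read_track_csv(config.tracks_csv)
        n_in = len(fixes)
        fixes, counts = tracks.filter_fixes(
            fixes, config.site_lat, config.site_lon,
            max_accuracy=config.max_accuracy_m,
            max_speed=config.max_speed_ms,
            min_solar_elevation=config.min_solar_elevation_deg)
        report["filters"] = {"input_fixes": n_in, "retained": len(fixes),
                             "removed": counts}
    except Exception as e:
        raise RuntimeError(f"tracks stage failed: {e}") from e

    aicc_tables = {}
    full_fits = {}
    all_strata = []
    try:
        stage("issa")
        for bird, df in fixes.groupby("bird_id", sort=True):
            observed = tracks.steps_from_fixes(df, config.interval_s,
                                               config.tolerance_s)
            if len(observed) < 30:
                log.warning("bird %s: too few steps (%d); skipped", bird,
                            len(observed))
                continue
            rng = _bird_rng(config.seed, str(bird))
            strata, kernel = prepare_bird_strata(observed, habitat, elev,
                                                 tide, config, rng)
            all_strata.append(strata)
            fits = issa.fit_candidates(strata)
            bird_report = {
                "n_strata": int(fits[0].n_strata),
                "kernel": dataclasses.asdict(kernel),
                "steps_by_end_wetland":
                    steps_by_end_wetland(strata).to_dict(),
            }
            bad = [f for f in fits if not f.converged]
            if any(f.model == "full" and not f.converged for f in fits):
                report["excluded_birds"].append(str(bird))
                bird_report["excluded_for_separation"] = True
                bird_report["non_converged_models"] = [f.model for f in bad]
                report["birds"][str(bird)] = bird_report
                continue
            conv = [f for f in fits if f.converged]
            table = issa.rank_aicc(conv)
            aicc_tables[str(bird)] = table
            table.to_csv(out / f"aicc_{bird}.csv", index=False)
            for f in conv:
                f.save(out / f"fit_{bird}_{f.model}.json")
            full = next(f for f in conv if f.model == "full")
            full_fits[str(bird)] = full

            # Movement model: full + step-length terms; corrected kernels.
            mfit = issa.fit_clogit(strata, issa.movement_spec())
            corrected = {}
            if mfit.converged:
                mfit.save(out / f"fit_{bird}_movement.json")
                for w in CLASS_NAMES:
                    try:
                        ck = issa.corrected_kernel(kernel, mfit, w)
                        corrected[w] = dataclasses.asdict(ck)
                    except ValueError as err:
                        corrected[w] = {"error": str(err)}
            bird_report["corrected_kernels"] = corrected

            # RSS curves from the best-supported converged model (use the
            # full model, which carries every contrast).
            depths = np.round(np.arange(config.depth_window[0],
                                        config.depth_window[1] + 1e-9, 0.05), 10)
            rss_rows = []
            for w in CLASS_NAMES[1:]:
                curve = issa.log_rss(full, w, depths,
                                     depth_window=config.depth_window)
                rss_rows.append(pd.DataFrame({
                    "wetland": w, "depth": curve.depths,
                    "log_rss": curve.log_rss,
                    "ci_lower": curve.ci_lower, "ci_upper": curve.ci_upper,
                }))
            pd.concat(rss_rows, ignore_index=True).to_csv(
                out / f"rss_{bird}.csv", index=False)
            report["birds"][str(bird)] = bird_report
    except Exception as e:
        raise RuntimeError(f"issa stage failed: {e}") from e

    if all_strata:
        dens = summarize_depth_density(pd.concat(all_strata, ignore_index=True),
                                       *config.depth_window)
        dens.to_csv(out / "depth_density.csv", index=False)

    if config.bursts_csv:
        try:
            stage("odba")
            bursts = tracks.read_bursts_csv(config.bursts_csv,
                                            config.burst_dialect)
            records = odba.process_bursts(bursts)
            records = records[~records["rejected"]]
            # Same daylight/non-flight context as fixes: ODBA records join
            # to the retained fixes by (bird, timestamp); the depth window
            # does not apply to the behavior analysis.
            key = fixes.set_index(["bird_id", "timestamp"])
            joined = records.join(
                key[["x", "y"]], on=["bird_id", "timestamp"], how="inner")
            code = habitat.class_code_at(joined["x"].to_numpy(),
                                         joined["y"].to_numpy())
            joined = joined[code >= 0].assign(
                wetland=[CLASS_NAMES[c] for c in code[code >= 0]])
            joined.drop(columns=["x", "y"]).to_csv(out / "odba.csv", index=False)

            stage("behavior")
            full_lmm = behavior.fit_lmm(joined, wetland_effect=True)
            null_lmm = behavior.fit_lmm(joined, wetland_effect=False)
            test = behavior.lrt(full_lmm, null_lmm)
            cis = behavior.fixed_effect_ci(joined, full_lmm)
            lmm_block = {
                "fit": full_lmm.to_dict(),
                "null": null_lmm.to_dict(),
                "lrt": dataclasses.asdict(test),
                "profile_ci": cis.to_dict(orient="records"),
            }
            (out / "lmm.json").write_text(json.dumps(lmm_block, indent=1))
            report["lmm"] = lmm_block
        except Exception as e:
            raise RuntimeError(f"behavior stage failed: {e}") from e

    report["aicc_best"] = {b: t["model"].iloc[0] for b, t in aicc_tables.items()}
    (out / "run_log.json").write_text(json.dumps(report, indent=1, default=str))
    return report
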