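"""Pipeline orchestration and summary tables.

``run_scenario`` drives the in-memory chain on a synthetic study
(calibrate -> convert -> register -> compare -> summarise); ``run_pipeline``
does the same from on-disk inputs described by a :class:`RunConfig`
(manifest CSV + calibration CSV + plane CSVs + film TIFFs), writing one
``result.json`` per comparison plus a ``summary.csv`` whose blocks mirror the
classic validation-table layout (plan dose, red/green film dose, plan and
measured FWHM per cone).

Replicate films of the same plane are compared individually and their
numeric results averaged, matching how replicate film measurements are
conventionally reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .commissioning import ConeId
from .compare import (
    ComparisonConfig,
    ComparisonResult,
    SummaryStats,
    compare_planes,
    summarize,
)
from .errors import ConfigError, DataError
from .film import (
    CalibrationCurve,
    CalibrationSet,
    FilmScan,
    film_to_dose,
    fit_calibration,
    read_film_scan,
)
from .planes import DosePlane, read_dose_plane
from .synthetic import ScenarioItem, SlabScenario

__all__ = [
    "RunConfig",
    "PipelineOutput",
    "calibrate_channels",
    "compare_item",
    "average_results",
    "run_scenario",
    "run_pipeline",
    "render_table",
]

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_COMMENT = "# conedose summary schema v1"
_KNOWN_CONFIG_KEYS = {
    "input_dir", "out_dir", "channels", "energies", "cones",
    "mask_fraction", "centroid_threshold_fraction", "seed", "verbosity",
}


@dataclass
class RunConfig:
    """Configuration of a file-based pipeline run."""

    input_dir: str
    out_dir: str
    channels: tuple[str, ...] = ("red", "green")
    energies: Optional[tuple[str, ...]] = None
    cones: Optional[tuple[float, ...]] = None
    mask_fraction: float = 0.8
    centroid_threshold_fraction: float = 0.5
    seed: Optional[int] = None
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        unknown = set(payload) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "input_dir" not in payload or "out_dir" not in payload:
            raise ConfigError("config requires input_dir and out_dir")
        cfg = cls(**payload)
        if not Path(cfg.input_dir).exists():
            raise ConfigError(f"input_dir does not exist: {cfg.input_dir}")
        return cfg

    def comparison_config(self) -> ComparisonConfig:
        return ComparisonConfig(
            mask_fraction=self.mask_fraction,
            centroid_threshold_fraction=self.centroid_threshold_fraction,
        )


def calibrate_channels(
    cal: CalibrationSet, channels=("red", "green")
) -> dict[str, CalibrationCurve]:
    """Fit the per-channel quartic calibration curves."""
    return {ch: fit_calibration(cal, ch) for ch in channels}


def compare_item(
    plan: DosePlane,
    films: list[FilmScan],
    curves: dict[str, CalibrationCurve],
    config: ComparisonConfig | None = None,
    energy: str = "",
    cone: Optional[ConeId] = None,
    label: str = "",
    profiles: str = "both",
    channels=("red", "green"),
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """Convert and compare each replicate film, then average the results."""
    per_film = []
    for scan in films:
        doses = {ch: film_to_dose(scan, curves[ch]) for ch in channels}
        per_film.append(
            compare_planes(plan, doses, config, energy=energy, cone=cone,
                           label=label, profiles=profiles)
        )
    return average_results(per_film), per_film


def average_results(results: list[ComparisonResult]) -> ComparisonResult:
    """Average replicate comparisons of the same plane into one result."""
    if not results:
        raise DataError("no results to average")
    first = results[0]
    out = ComparisonResult(energy=first.energy, cone=first.cone, label=first.label)
    out.fwhm_plan_h_mm = first.fwhm_plan_h_mm
    out.fwhm_plan_v_mm = first.fwhm_plan_v_mm
    out.mean80_plan_gy = first.mean80_plan_gy

    def _avg(getter):
        keys = getter(first).keys()
        return {k: float(np.mean([getter(r)[k] for r in results])) for k in keys}

    out.fwhm_meas_h_mm = _avg(lambda r: r.fwhm_meas_h_mm)
    out.fwhm_meas_v_mm = _avg(lambda r: r.fwhm_meas_v_mm)
    out.mean80_meas_gy = _avg(lambda r: r.mean80_meas_gy)
    out.pct_diff = _avg(lambda r: r.pct_diff)
    if all(r.pct_diff_rg is not None for r in results):
        out.pct_diff_rg = float(np.mean([r.pct_diff_rg for r in results]))
    out.centroid_shift_mm = {
        ch: tuple(np.mean([r.centroid_shift_mm[ch] for r in results], axis=0))
        for ch in first.centroid_shift_mm
    }
    return out


def _item_profiles(item: ScenarioItem) -> str:
    # arc films are profiled only perpendicular to gantry travel (the
    # y/vertical plane axis); static films in both directions
    return "v" if item.kind == "arc" else "both"


def run_scenario(
    scenario: SlabScenario,
    config: ComparisonConfig | None = None,
    channels=("red", "green"),
    kinds=("static", "arc"),
) -> tuple[list[ComparisonResult], SummaryStats]:
    """Full in-memory pipeline over a synthetic scenario."""
    curves = calibrate_channels(scenario.calibration, channels)
    results = []
    for item in scenario.items:
        if item.kind not in kinds:
            continue
        avg, _ = compare_item(
            item.plan, item.films, curves, config,
            energy=item.energy, cone=item.cone, label=item.depth_label,
            profiles=_item_profiles(item), channels=channels,
        )
        results.append(avg)
    return results, summarize(results, config)


@dataclass
class PipelineOutput:
    results: list[ComparisonResult]
    summary: SummaryStats
    result_paths: list[Path] = field(default_factory=list)
    summary_path: Optional[Path] = None


def _result_payload(res: ComparisonResult) -> dict:
    payload = asdict(res)
    payload["cone_mm"] = res.cone.nominal_diameter_mm if res.cone else None
    del payload["cone"]
    return payload


def run_pipeline(config: RunConfig) -> PipelineOutput:
    """File-based pipeline: calibrate -> convert -> register -> compare -> summarise.

    Expects in ``config.input_dir``: ``manifest.csv`` (kind, energy, cone_mm,
    depth, plan, film_1[, film_2]), ``calibration.csv`` (dose_gy,
    <channel>_counts columns), plane CSVs with JSON sidecars and film TIFFs.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = indir / "manifest.csv"
    cal_path = indir / "calibration.csv"
    for p in (manifest_path, cal_path):
        if not p.exists():
            raise DataError(f"pipeline stage 'load': missing {p}")
    cal_df = pd.read_csv(cal_path)
    measurements = [
        (
            float(row["dose_gy"]),
            {ch: float(row[f"{ch}_counts"]) for ch in config.channels},
        )
        for _, row in cal_df.iterrows()
    ]
    curves = calibrate_channels(
        CalibrationSet(measurements=measurements), config.channels
    )
    cmp_config = config.comparison_config()
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    results, result_paths = [], []
    for idx, row in manifest.iterrows():
        if config.energies and row["energy"] not in config.energies:
            continue
        if config.cones and float(row["cone_mm"]) not in config.cones:
            continue
        plan_path = indir / row["plan"]
        if not plan_path.exists():
            raise DataError(f"manifest row {idx}: missing plan file {row['plan']}")
        films = []
        for col in ("film_1", "film_2"):
            name = str(row.get(col, "") or "")
            if not name:
                continue
            fp = indir / name
            if not fp.exists():
                raise DataError(f"manifest row {idx}: missing film file {name}")
            films.append(read_film_scan(fp))
        if not films:
            raise DataError(f"manifest row {idx}: no film files listed")
        plan = read_dose_plane(plan_path)
        profiles = "v" if row["kind"] == "arc" else "both"
        avg, _ = compare_item(
            plan, films, curves, cmp_config,
            energy=str(row["energy"]), cone=ConeId(float(row["cone_mm"])),
            label=str(row["depth"]), profiles=profiles, channels=config.channels,
        )
        results.append(avg)
        rp = outdir / f"result_{idx:03d}.json"
        rp.write_text(json.dumps(_result_payload(avg), indent=2))
        result_paths.append(rp)
        log.info("compared row %d: %s %s mm %s", idx, row["energy"],
                 row["cone_mm"], row["depth"])
    if not results:
        raise DataError("pipeline produced no comparisons (empty selection?)")
    summary = summarize(results, cmp_config)
    table = render_table(results, cmp_config)
    summary_path = outdir / "summary.csv"
    with open(summary_path, "w") as fh:
        fh.write(SUMMARY_SCHEMA_COMMENT + "\n")
        table.to_csv(fh)
    (outdir / "summary_stats.json").write_text(json.dumps(asdict(summary), indent=2))
    return PipelineOutput(results=results, summary=summary,
                          result_paths=result_paths, summary_path=summary_path)


def render_table(
    results: list[ComparisonResult],
    config: ComparisonConfig | None = None,
) -> pd.DataFrame:
    """Validation-table rendering: one block per energy/depth, columns per cone.

    Rows per block: plan dose, red/green film dose, plan FWHM and red-channel
    FWHM (horizontal where available, else vertical), rounded to 0.1.
    """
    if not results:
        raise DataError("cannot render an empty result list")
    config = config or ComparisonConfig()

    def r1(v):
        return None if v is None else round(v, 1)

    blocks: dict[tuple[str, str], dict] = {}
    for res in results:
        key = (res.energy, res.label)
        block = blocks.setdefault(key, {})
        col = f"{res.cone} mm" if res.cone else "?"
        fwhm_plan = res.fwhm_plan_h_mm if res.fwhm_plan_h_mm is not None \
            else res.fwhm_plan_v_mm
        fwhm_red = res.fwhm_meas_h_mm.get("red", res.fwhm_meas_v_mm.get("red"))
        red = res.mean80_meas_gy.get("red")
        green = res.mean80_meas_gy.get("green")
        block[col] = {
            "Dose Plan (Gy)": r1(res.mean80_plan_gy),
            "Dose Red/Green (Gy)": (
                f"{r1(red)}/{r1(green)}" if red is not None and green is not None
                else ""
            ),
            "FWHM Plan (mm)": r1(fwhm_plan),
            "FWHM Red (mm)": r1(fwhm_red),
        }
    rows = []
    for (energy, label), cols in blocks.items():
        any_col = next(iter(cols.values()))
        for metric in any_col:
            row = {"block": f"{energy} {label}".strip(), "metric": metric}
            row.update({c: cols[c].get(metric) for c in cols})
            rows.append(row)
    return pd.DataFrame(rows).set_index(["block", "metric"])
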