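"""Config-driven end-to-end analysis runs and population summaries."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import border as _border
from . import classify as _classify
from . import ebr as _ebr
from . import maps as _maps
from . import session as _session
from . import temporal as _temporal
from .classify import CellReport, NullDistribution, ShuffleEngine
from .session import SpikeTrain, TrajectorySession

__all__ = ["RunConfig", "RunResult", "run_pipeline", "summarize",
           "reports_to_frame", "render_summary"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables; defaults mirror the analysis modules."""

    # inputs (either files or a synthetic population)
    position_path: str | None = None
    geometry_path: str | None = None
    spikes_path: str | None = None
    waveforms_path: str | None = None
    labels_path: str | None = None     # optional unit metadata (hemisphere)
    out_dir: str | None = None
    seed: int = 0
    # maps
    bin_size_cm: float = _maps.BIN_SIZE_CM
    sigma_bins: float = _maps.SIGMA_BINS
    hd_bin_deg: float = _maps.HD_BIN_DEG
    hd_sigma_bins: float = _maps.HD_SIGMA_BINS
    band_cm: float = _maps.WALL_BAND_CM
    min_speed: float = _session.MIN_SPEED_CM_S
    # border / gate
    field_threshold_frac: float = _border.FIELD_THRESHOLD_FRAC
    min_field_area_cm2: float = _border.MIN_FIELD_AREA_CM2
    wall_covered_frac: float = _border.WALL_COVERED_FRAC
    n_shuffles: int = _classify.N_SHUFFLES
    min_shift_s: float = _classify.MIN_SHIFT_S
    # EBR
    ebr_max_dist_cm: float = _ebr.EBR_MAX_DIST_CM
    ebr_angle_bin_deg: float = _ebr.EBR_ANGLE_BIN_DEG
    ebr_dist_bin_cm: float = _ebr.EBR_DIST_BIN_CM
    ebr_sigma_bins: float = _ebr.EBR_SIGMA_BINS
    ebr_reference: str = "head"
    # theta
    acg_bin_ms: float = _temporal.ACG_BIN_MS
    acg_span_ms: float = _temporal.ACG_SPAN_MS
    tri_threshold: float = _temporal.TRI_THRESHOLD
    # population test
    p0: float = 0.01

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class RunResult:
    reports: list[CellReport]
    null: NullDistribution | None
    summary: dict
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])


def analyze_cells(session: TrajectorySession, cells: list[SpikeTrain],
                  config: RunConfig,
                  waveform_fs: float | None = None) -> RunResult:
    """Run the full per-unit analysis on already-loaded data."""
    rng = np.random.default_rng(config.seed)
    engine = ShuffleEngine(
        session, bin_size=config.bin_size_cm, sigma_bins=config.sigma_bins,
        min_speed=config.min_speed,
        threshold_frac=config.field_threshold_frac,
        min_area_cm2=config.min_field_area_cm2)
    mask = engine.mask

    null = _classify.build_null(
        [session] * len(cells), cells, n_shuffles=config.n_shuffles,
        rng=rng, min_shift=config.min_shift_s,
        engines=[engine] * len(cells)) if cells else None

    reports = []
    for cell in cells:
        rep = CellReport(unit_id=cell.unit_id, hemisphere=cell.hemisphere)
        try:
            _, st = _session.speed_filter(session, cell.spike_times,
                                          config.min_speed)
            rm = _maps.rate_map(session, st, config.bin_size_cm,
                                config.sigma_bins, mask=mask,
                                occupancy=engine.occ)
            rep.mean_rate = cell.mean_rate(session.duration)
            rep.peak_rate = rm.peak_rate
            bs = _border.border_score(rm, session.arena,
                                      config.field_threshold_frac,
                                      config.min_field_area_cm2)
            rep.border_score, rep.cM, rep.dm = bs.b, bs.cM, bs.dm
            rep.n_walls = _border.wall_count(bs.fields, session.arena,
                                             config.wall_covered_frac)
            rep.stability = _maps.split_half_stability(
                session, st, config.bin_size_cm, config.sigma_bins,
                mask=mask)
            rep.is_border = _classify.gate_border(rep.border_score,
                                                  rep.stability, null)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _classify.cw_ccw_ratio(session, st, session.arena,
                                             config.band_cm, mask=mask)
            rep.fr_cw_ccw = res.fr_ratio
            rep.time_cw_ccw = res.time_ratio
            if rep.is_border:
                rep.subtype = _classify.classify_subtype(res.fr_ratio)
                e = _ebr.egocentric_boundary_ratemap(
                    session, st, session.arena,
                    reference=config.ebr_reference,
                    max_dist=config.ebr_max_dist_cm,
                    angle_bin_deg=config.ebr_angle_bin_deg,
                    dist_bin_cm=config.ebr_dist_bin_cm,
                    sigma_bins=config.ebr_sigma_bins, mask=mask)
                rep.ebr_mvl, rep.ebr_pref_angle = e.mvl, e.pref_angle
            if cell.n_spikes >= 2:
                acg = _temporal.spike_autocorrelogram(
                    cell, config.acg_bin_ms, config.acg_span_ms)
                th = _temporal.theta_rhythmicity_index(
                    acg, threshold=config.tri_threshold)
                rep.tri, rep.theta_peak_hz = th.tri, th.theta_peak_hz
                rep.is_theta = th.is_theta
            if cell.waveform is not None and waveform_fs:
                width = _classify.peak_to_trough_us(cell.waveform,
                                                    waveform_fs)
                rep.cell_class = _classify.classify_waveform(
                    rep.mean_rate, width)
        except (ValueError, ZeroDivisionError) as err:
            log.warning("unit %s: %s", cell.unit_id, err)
        reports.append(rep)

    summary = summarize(reports, config.p0)
    if null is not None:
        summary["p99_border"] = null.p99_border
        summary["p99_stability"] = null.p99_stability
    return RunResult(reports, null, summary, reports_to_frame(reports))


def run_pipeline(config: RunConfig) -> RunResult:
    """Load the configured inputs, analyze every unit, write outputs."""
    if config.position_path is None:
        raise ValueError("config.position_path is required")
    session = _session.load_session(config.position_path,
                                    config.geometry_path)
    hemispheres = None
    if config.labels_path:
        meta = pd.read_csv(config.labels_path, dtype={"unit_id": str})
        if "hemisphere" in meta.columns:
            hemispheres = dict(zip(meta["unit_id"], meta["hemisphere"]))
    cells = _session.load_spikes(config.spikes_path,
                                 hemispheres=hemispheres) \
        if config.spikes_path else []
    waveform_fs = None
    if config.waveforms_path:
        waves, waveform_fs = _session.load_waveforms(config.waveforms_path)
        for c in cells:
            c.waveform = waves.get(c.unit_id)
    if not cells:
        warnings.warn("no spike trains found; producing an empty report")
        return RunResult([], None, {}, pd.DataFrame())
    result = analyze_cells(session, cells, config, waveform_fs)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.frame.to_csv(out / "cell_report.csv", index=False,
                            float_format="%.6g")
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, default=float)
        with open(out / "summary.txt", "w") as fh:
            fh.write(render_summary(result.summary))
    return result


def _pct(k: int, n: int) -> float:
    """Percentage k/n rounded to 2 decimal places (NaN for empty n)."""
    return round(100.0 * k / n, 2) if n else np.nan


def summarize(reports, p0: float = 0.01) -> dict:
    """Population summary: border fraction and binomial z against chance,
    subtype and theta fractions, wall counts and lateralization."""
    if not len(reports):
        raise ValueError("no reports to summarize")
    if isinstance(reports, pd.DataFrame):
        df = reports
        reports = [CellReport(**{k: v for k, v in row.items()
                                 if k in CellReport.__dataclass_fields__})
                   for row in df.to_dict("records")]
    n = len(reports)
    borders = [r for r in reports if r.is_border]
    k = len(borders)
    out = {
        "n_units": n, "n_border": k,
        "border_pct": _pct(k, n),
        "binomial_z": round(_classify.binomial_ztest(k, n, p0), 2)
        if n else np.nan,
        "p0": p0,
    }
    for sub in ("allocentric", "left_ego", "right_ego"):
        ks = sum(r.subtype == sub for r in borders)
        out[f"n_{sub}"] = ks
        out[f"{sub}_pct"] = _pct(ks, k)
    four = sum(r.n_walls >= 4 for r in borders)
    out["n_four_wall"] = four
    out["four_wall_pct"] = _pct(four, k)
    for cls in ("RS", "FS", "unclassified"):
        kc = sum(r.cell_class == cls for r in borders)
        out[f"{cls}_border_pct"] = _pct(kc, k)
    tf = _temporal.theta_fractions([r.is_theta for r in reports],
                                   [r.is_border for r in reports])
    out["theta_border_pct"] = _pct(tf["n_theta_border"], tf["n_border"])
    out["theta_nonborder_pct"] = _pct(tf["n_theta_nonborder"],
                                      tf["n_nonborder"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, chi2 = _classify.lateralization_table(reports)
    out["lateralization_table"] = table.tolist()
    out["lateralization_chi2"] = chi2
    return out


def render_summary(summary: dict) -> str:
    lines = [
        "Population summary",
        "------------------",
        f"units analysed:       {summary.get('n_units', 0)}",
        f"border cells:         {summary.get('n_border', 0)} "
        f"({summary.get('border_pct')}%)",
        f"binomial z vs p0={summary.get('p0')}: "
        f"{summary.get('binomial_z')}",
        f"  allocentric:        {summary.get('n_allocentric')} "
        f"({summary.get('allocentric_pct')}%)",
        f"  left egocentric:    {summary.get('n_left_ego')} "
        f"({summary.get('left_ego_pct')}%)",
        f"  right egocentric:   {summary.get('n_right_ego')} "
        f"({summary.get('right_ego_pct')}%)",
        "four-wall fields (coverage >= 0.25 per wall, package criterion): "
        f"{summary.get('n_four_wall')} ({summary.get('four_wall_pct')}%)",
        f"theta-rhythmic border cells:    {summary.get('theta_border_pct')}%",
        f"theta-rhythmic nonborder cells: "
        f"{summary.get('theta_nonborder_pct')}%",
        f"lateralization chi2:  {summary.get('lateralization_chi2')}",
    ]
    return "\n".join(lines) + "\n"
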