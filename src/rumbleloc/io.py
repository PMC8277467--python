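"""File handling, run configuration and the end-to-end pipeline.

Data layout expected on disk::

    <data_dir>/
        stations.csv            id,x_m,y_m,modality
        catalogue.csv           event_id,start_utc,end_utc
        <STATION>_<modality>.wav (+ .wav.json sidecar)

Timestamps are ISO-8601 UTC or plain seconds on the shared station clock;
positions are a local planar metric frame in metres (project geographic
coordinates externally).  The pipeline runs signal -> tdoa -> locate ->
metrics per event; a failure (e.g. a correlation-prominence rejection)
aborts that event only and is logged with the failing criterion.
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

from . import locate as loc
from . import signal as sig
from .geometry import StationGeometry, station_array
from .metrics import ResidualTable, summarize
from .tdoa import EventRejected, EventWindow, build_tdoa_set, default_max_lag

log = logging.getLogger("rumbleloc")

__all__ = ["RunConfig", "read_stations", "read_catalogue", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated run settings; unknown keys in a YAML file are rejected."""

    # signal
    window_length_s: float = 0.5
    overlap: float = 0.9
    f_max_hz: float = 100.0
    analysis_rate_hz: float = 400.0
    enhancement: dict = field(
        default_factory=lambda: {"gradient_scale": 1.0, "integration_scale": 3.0,
                                 "exponent": 1.0, "floor": 0.05}
    )
    # tdoa
    max_lag_s: float | None = None  # None -> 1.5 * aperture / 200 m/s
    min_prominence: float = 0.1
    # locate
    tdoa_sigma_s: float | None = None  # None -> one spectrogram time bin
    wavespeed_grid: dict = field(default_factory=lambda: dict(loc._DEFAULT_GRIDS))
    wavespeed_prior: dict = field(default_factory=lambda: dict(loc._DEFAULT_V_PRIORS))
    position_prior: tuple | None = None
    n_samples: int = 4000
    seed: int = 0

    def enhancement_params(self) -> sig.EnhancementParams:
        e = self.enhancement
        return sig.EnhancementParams(
            gradient_scale=e.get("gradient_scale", 1.0),
            integration_scale=e.get("integration_scale", 3.0),
            coherence_exponent=e.get("exponent", 1.0),
            floor=e.get("floor", 0.05),
        )

    def solver_config(self) -> loc.SolverConfig:
        dt = self.window_length_s * (1.0 - self.overlap)
        return loc.SolverConfig(
            wavespeed_grid={k: np.asarray(v, dtype=float) for k, v in self.wavespeed_grid.items()},
            tdoa_sigma=self.tdoa_sigma_s if self.tdoa_sigma_s is not None else dt,
            position_prior=tuple(self.position_prior) if self.position_prior else None,
            wavespeed_prior={k: tuple(v) for k, v in self.wavespeed_prior.items()},
            n_samples=self.n_samples,
            rng_seed=self.seed,
        )


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_stations(path: str | Path) -> list[StationGeometry]:
    """Load a station-geometry CSV (columns id, x_m, y_m, modality)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no stations")
    required = {"id", "x_m", "y_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate station ids {dups}")
    for col in ("x_m", "y_m"):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number) or (
            pd.to_numeric(df[col], errors="coerce").isna().any()
        ):
            raise ValueError(f"{path}: non-numeric coordinates in column {col}")
    modality = df["modality"] if "modality" in df.columns else ["both"] * len(df)
    return [
        StationGeometry(str(r_id), float(x), float(y), str(m))
        for r_id, x, y, m in zip(df["id"], df["x_m"], df["y_m"], modality)
    ]


def _parse_time(value) -> float:
    """ISO-8601 -> epoch seconds; numeric strings/floats pass through."""
    try:
        return float(value)
    except (TypeError, ValueError):
        ts = pd.Timestamp(value)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        return float(ts.timestamp())


def read_catalogue(path: str | Path) -> pd.DataFrame:
    """Event catalogue CSV: event_id, start_utc, end_utc (ISO or seconds)."""
    df = pd.read_csv(path)
    missing = {"event_id", "start_utc", "end_utc"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["start_s"] = df["start_utc"].map(_parse_time)
    df["end_s"] = df["end_utc"].map(_parse_time)
    if (df["end_s"] <= df["start_s"]).any():
        raise ValueError(f"{path}: event end must be after start")
    return df


def _cut_window(w: sig.Waveform, start: float, end: float) -> sig.Waveform:
    i0 = max(0, int(round((start - w.start_time) * w.sampling_rate)))
    i1 = min(w.n_samples, int(round((end - w.start_time) * w.sampling_rate)))
    if i1 - i0 < 8:
        raise ValueError(f"window [{start}, {end}] outside record of {w.station_id}")
    return dataclasses.replace(
        w, samples=w.samples[:, i0:i1], start_time=w.start_time + i0 / w.sampling_rate
    )


def event_window_from_waveforms(
    waveforms: dict, event_id: str, start: float, end: float, modality: str, cfg: RunConfig
) -> EventWindow:
    """Cut, stack, decimate (acoustic), transform and enhance per station."""
    specs = {}
    params = cfg.enhancement_params()
    for (sid, mod), w in waveforms.items():
        if mod != modality:
            continue
        cut = _cut_window(w, start, end)
        cut = sig.stack_channels(cut)
        if modality == "acoustic" and cut.sampling_rate > cfg.analysis_rate_hz:
            cut = sig.decimate_waveform(cut, cfg.analysis_rate_hz)
        s = sig.compute_spectrogram(cut, cfg.window_length_s, cfg.overlap, cfg.f_max_hz)
        specs[sid] = sig.enhance_spectrogram(s, params)
    if not specs:
        raise ValueError(f"event {event_id!r}: no {modality} records in window")
    return EventWindow(event_id=event_id, spectrograms=specs)


def load_waveform_dir(data_dir: str | Path) -> dict:
    """Read every <STATION>_<modality>.wav in a directory."""
    data_dir = Path(data_dir)
    out = {}
    for p in sorted(data_dir.glob("*.wav")):
        w = sig.read_wav(p)
        out[(w.station_id, w.modality)] = w
    if not out:
        raise ValueError(f"{data_dir}: no .wav records found")
    return out


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    modality: str = "both",
    method: str = "both",
) -> pd.DataFrame:
    """Full pipeline: waveforms + catalogue -> estimates CSV + report JSON.

    ``modality``/``method`` select which of the five estimate variants are
    produced (det/prob x seismic/acoustic, plus joint when both modalities
    and the probabilistic method are requested).  Events failing a selection
    criterion are skipped and listed, with the reason, in the report.
    """
    cfg = config or RunConfig()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stations = read_stations(data_dir / "stations.csv")
    catalogue = read_catalogue(data_dir / "catalogue.csv")
    waveforms = load_waveform_dir(data_dir)
    solver_cfg = cfg.solver_config()
    max_lag = cfg.max_lag_s or default_max_lag(station_array(stations))

    modalities = ["seismic", "acoustic"] if modality == "both" else [modality]
    methods = ["det", "prob"] if method == "both" else [method]
    rows, rejected, tdoa_records = [], [], []

    for _, ev in catalogue.iterrows():
        eid = str(ev["event_id"])
        tdoa_sets = {}
        try:
            for mod in modalities:
                win = event_window_from_waveforms(
                    waveforms, eid, ev["start_s"], ev["end_s"], mod, cfg
                )
                tset = build_tdoa_set(win, max_lag, cfg.min_prominence, modality=mod)
                tdoa_sets[mod] = tset
                tdoa_records.append(tset.to_dict())
                log.info("event %s %s: reference %s, lags %s", eid, mod,
                         tset.reference_station, np.round(tset.lags, 4).tolist())
        except (EventRejected, ValueError) as err:
            rejected.append({"event_id": eid, "reason": str(err)})
            log.warning("event %s rejected: %s", eid, err)
            continue

        for mod, tset in tdoa_sets.items():
            model = loc.TdoaLocationModel(tset, stations, solver_cfg)
            if "det" in methods:
                best = model.fit().best
                rows.append(_estimate_row(eid, "det", mod, best))
            if "prob" in methods:
                best = model.fit_probabilistic().best
                rows.append(_estimate_row(eid, "prob", mod, best))
        if len(tdoa_sets) == 2 and "prob" in methods:
            joint = loc.JointTdoaLocationModel(
                tdoa_sets["seismic"], tdoa_sets["acoustic"], stations, solver_cfg
            ).fit().best
            rows.append(_estimate_row(eid, "joint", "both", joint))

    estimates = pd.DataFrame(
        rows, columns=["event_id", "method", "modality", "x", "y", "v", "residual"]
    )
    estimates.to_csv(out_dir / "estimates.csv", index=False)
    (out_dir / "tdoa_sets.json").write_text(json.dumps(tdoa_records, indent=2))
    report: dict = {"n_events": len(catalogue), "n_located": estimates["event_id"].nunique()
                    if not estimates.empty else 0, "rejected": rejected}
    residual_table = _residual_table(estimates)
    if residual_table is not None and residual_table.n_events >= 2:
        report["summary"] = summarize(residual_table).to_dict()
        residual_table.to_csv(out_dir / "residual_table.csv")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return estimates


def _estimate_row(eid: str, method: str, mod: str, e: loc.LocationEstimate) -> dict:
    return {
        "event_id": eid, "method": method, "modality": mod,
        "x": float(e.x[0]), "y": float(e.x[1]), "v": float(e.v),
        "residual": float(e.residual),
    }


def _residual_table(estimates: pd.DataFrame) -> ResidualTable | None:
    """Pivot the estimates into the five-column per-event residual table."""
    if estimates.empty:
        return None
    key = estimates.apply(
        lambda r: ("prob_joint" if r["method"] == "joint"
                   else f"{r['method']}_{r['modality']}"), axis=1
    )
    wide = estimates.assign(column=key).pivot_table(
        index="event_id", columns="column", values="residual"
    )
    needed = {"det_acoustic", "det_seismic", "prob_acoustic", "prob_seismic", "prob_joint"}
    if not needed.issubset(wide.columns) or wide[list(needed)].isna().any().any():
        return None
    return ResidualTable(wide.reset_index())
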