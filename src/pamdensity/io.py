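"""CSV readers/writers for the pipeline's tabular interchange formats.

All on-disk timestamps are ISO-8601 UTC; in memory everything is seconds
since the Unix epoch (UTC).
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import AcousticScenario, DetectionFunction, GroupBehavior, SimConfig
from .multipliers import DiveCycle, TagRecord

__all__ = [
    "read_click_log", "write_click_log",
    "read_effort", "write_effort",
    "read_tag_record", "write_tag_record",
    "read_bouts", "write_bouts",
    "write_weekly_counts", "read_weekly_counts",
    "write_detection_function", "read_detection_summary",
    "write_multipliers",
    "load_scenario_config",
]


def _to_seconds(series: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def _to_iso(seconds) -> pd.Series:
    return pd.to_datetime(np.asarray(seconds, dtype=float) * 1e9, utc=True).strftime(
        "%Y-%m-%dT%H:%M:%S.%f").str.rstrip("0").str.rstrip(".") + "Z"


def read_click_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({
        "time_s": _to_seconds(df["time_iso8601"]),
        "received_level_dbpp": df["received_level_dbpp"].astype(float),
        "species": df["species"], "site": df["site"],
    })


def write_click_log(clicks: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "time_iso8601": _to_iso(clicks["time_s"]),
        "received_level_dbpp": clicks["received_level_dbpp"],
        "species": clicks["species"], "site": clicks["site"],
    })
    out.to_csv(path, index=False)


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({
        "site": df["site"],
        "start": _to_seconds(df["start_iso8601"]),
        "end": _to_seconds(df["end_iso8601"]),
    })


def write_effort(effort: pd.DataFrame, path) -> None:
    pd.DataFrame({
        "site": effort["site"],
        "start_iso8601": _to_iso(effort["start"]),
        "end_iso8601": _to_iso(effort["end"]),
    }).to_csv(path, index=False)


def read_tag_record(path) -> TagRecord:
    """Tag CSV: ``cycle_id,duration_s,click_positive_seconds`` where the
    last column is a semicolon-separated list of second indices, or the long
    form ``cycle_id,second_index`` plus a ``duration_s`` column."""
    df = pd.read_csv(path)
    cycles = []
    if "click_positive_seconds" in df.columns:
        for _, row in df.sort_values("cycle_id").iterrows():
            raw = row["click_positive_seconds"]
            secs = (np.array([int(s) for s in str(raw).split(";") if s != ""])
                    if pd.notna(raw) and str(raw) != "" else np.empty(0, dtype=int))
            cycles.append(DiveCycle(int(row["duration_s"]), secs))
    elif "second_index" in df.columns:
        for _, grp in df.groupby("cycle_id", sort=True):
            cycles.append(DiveCycle(int(grp["duration_s"].iloc[0]),
                                    grp["second_index"].to_numpy(dtype=int)))
    else:
        raise ValueError("unrecognised tag-record format")
    return TagRecord(cycles)


def write_tag_record(tag: TagRecord, path) -> None:
    rows = [{"cycle_id": i, "duration_s": c.duration,
             "click_positive_seconds": ";".join(map(str, c.click_positive_seconds))}
            for i, c in enumerate(tag.cycles)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bouts(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bouts(bouts: pd.DataFrame, path) -> None:
    bouts.to_csv(path, index=False)


def write_weekly_counts(weekly: pd.DataFrame, path) -> None:
    out = weekly.copy()
    out["week_start"] = pd.to_datetime(out["week_start"] * 1e9, utc=True).dt.date
    out.to_csv(path, index=False)


def read_weekly_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["week_start"], utc=True)
    df["week_start"] = ts.astype("int64") / 1e9
    return df


def write_detection_function(detfun: DetectionFunction, path,
                             summary_path=None) -> None:
    detfun.to_frame().to_csv(path, index=False)
    if summary_path is not None:
        pd.DataFrame([detfun.summary()]).to_csv(summary_path, index=False)


def read_detection_summary(path) -> dict:
    row = pd.read_csv(path).iloc[0]
    return {"p_k": float(row["p_k"]), "cv": float(row["cv"]),
            "w_km": float(row["w_km"])}


def write_multipliers(rows, path) -> None:
    """Write a ``species,site,quantity,value,cv`` multiplier table."""
    pd.DataFrame(rows, columns=["species", "site", "quantity", "value", "cv"]
                 ).to_csv(path, index=False)


def load_scenario_config(path):
    """Load an INI scenario config into simulation parameter objects.

    Sections: ``[scenario]`` (acoustic/geometry), optional ``[behavior]``
    (group sweep) and ``[sim]`` (Monte Carlo sizes).  Interval parameters
    are comma-separated pairs.  Returns ``(AcousticScenario, GroupBehavior,
    SimConfig)``.
    """
    cp = configparser.ConfigParser()
    read = cp.read(Path(path))
    if not read:
        raise FileNotFoundError(path)

    def pair(section, key, default):
        if cp.has_option(section, key):
            lo, hi = (float(v) for v in cp.get(section, key).split(","))
            return (lo, hi)
        return default

    s = cp["scenario"]
    scenario = AcousticScenario(
        source_level_mean=s.getfloat("source_level_mean"),
        peak_frequency=s.getfloat("peak_frequency"),
        source_level_sd=s.getfloat("source_level_sd", 3.0),
        directivity_index_range=pair("scenario", "directivity_index_range", (24.0, 28.0)),
        detection_threshold=s.getfloat("detection_threshold", 121.0),
        absorption=s.getfloat("absorption", None),
        receiver_altitude=s.getfloat("receiver_altitude", 10.0),
        animal_altitude_range=pair("scenario", "animal_altitude_range", (175.0, 225.0)),
        monitoring_radius_w=s.getfloat("monitoring_radius_w", 4.0),
        pitch_sd_range=pair("scenario", "pitch_sd_range", (5.0, 15.0)),
        beam_loss_floor=s.getfloat("beam_loss_floor", 40.0),
    )
    behavior = GroupBehavior(
        azimuth_sweep_range=pair("behavior", "azimuth_sweep_range", (140.0, 160.0)),
        elevation_sweep_foraging_range=pair("behavior", "elevation_sweep_foraging_range", (55.0, 65.0)),
        elevation_sweep_descent_range=pair("behavior", "elevation_sweep_descent_range", (10.0, 15.0)),
        descent_fraction=(cp.getfloat("behavior", "descent_fraction")
                          if cp.has_option("behavior", "descent_fraction") else 0.0),
    )
    sim = SimConfig(
        iterations=(cp.getint("sim", "iterations")
                    if cp.has_option("sim", "iterations") else 500),
        animals_per_iteration=(cp.getint("sim", "animals_per_iteration")
                               if cp.has_option("sim", "animals_per_iteration") else 10_000),
        range_bin=(cp.getfloat("sim", "range_bin")
                   if cp.has_option("sim", "range_bin") else 100.0),
        seed=(cp.getint("sim", "seed") if cp.has_option("sim", "seed") else None),
    )
    return scenario, behavior, sim
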