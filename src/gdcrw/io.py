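"""Telemetry CSV input/output and deterministic fixture generation.

The telemetry dialect is a comma-separated UTF-8 file with a header and the
columns ``id, date, lc, lat, lon`` (any order): one row per fix with an
ISO-8601 timestamp (or a bare number, read as fractional hours), an Argos
location class (3/2/1/0/A/B/Z, or G for GPS/Gaussian-grade), and the
coordinates.  On load, rows are sorted by time within track, class-Z rows
are dropped (and counted in the log), and timestamps are converted to
fractional hours since each track's first record.  The first model
coordinate is latitude.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ObservationSet
from .noise import NoiseModel, default_argos_noise
from .params import MovementParams
from .simulate import sample_observation_times, simulate_continuous, simulate_observations

__all__ = ["read_telemetry", "write_telemetry", "make_fixture"]

logger = logging.getLogger("gdcrw")

_REQUIRED = {"id", "date", "lc", "lat", "lon"}
_VALID_CLASSES = {"3", "2", "1", "0", "A", "B", "Z", "G"}
_EPOCH = pd.Timestamp("2020-01-01T00:00:00")


def _parse_times(raw: pd.Series) -> np.ndarray:
    """Hours since the first record; accepts ISO-8601 or bare numbers."""
    try:
        hours = pd.to_numeric(raw)
        return hours.to_numpy(float)
    except (ValueError, TypeError):
        pass
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable timestamp in row {row + 2}: {raw.iloc[row]!r}")
    return ((ts - ts.iloc[0]).dt.total_seconds() / 3600.0).to_numpy(float)


def read_telemetry(path, delimiter: str = ",") -> list[ObservationSet]:
    """Read a telemetry CSV; returns one :class:`ObservationSet` per track."""
    df = pd.read_csv(path, delimiter=delimiter)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"missing telemetry columns: {sorted(missing)}")
    df["lc"] = df["lc"].astype(str).str.strip().str.upper()
    bad = ~df["lc"].isin(_VALID_CLASSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown location class in row {row + 2}: {df['lc'].iloc[row]!r}")
    n_z = int((df["lc"] == "Z").sum())
    if n_z:
        logger.info("dropping %d class-Z record(s)", n_z)
        df = df[df["lc"] != "Z"]
    out = []
    for tid, g in df.groupby("id", sort=False):
        times = _parse_times(g["date"].reset_index(drop=True))
        order = np.argsort(times, kind="stable")
        times = times[order] - times[order][0]
        coords = g[["lat", "lon"]].to_numpy(float)[order]
        classes = g["lc"].to_numpy(object)[order]
        out.append(ObservationSet(times, coords, classes, str(tid)))
    return out


def write_telemetry(obs: ObservationSet, path, iso_timestamps: bool = True) -> None:
    """Write an :class:`ObservationSet` in the telemetry CSV dialect."""
    if iso_timestamps:
        dates = (_EPOCH + pd.to_timedelta(obs.times, unit="h")).strftime(
            "%Y-%m-%dT%H:%M:%S.%f"
        )
    else:
        dates = obs.times
    pd.DataFrame(
        {
            "id": obs.track_id,
            "date": dates,
            "lc": obs.classes,
            "lat": obs.coords[:, 0],
            "lon": obs.coords[:, 1],
        }
    ).to_csv(path, index=False)


_FIXTURE_PARAMS = {
    "persistent": dict(gamma=0.9, sigma=float(np.exp(-2)), theta=0.0, mu=(0.0, 0.0)),
    "tortuous": dict(gamma=0.6, sigma=float(np.exp(-2)), theta=float(np.pi / 3), mu=(0.0, 0.0)),
    "drifted": dict(gamma=0.8, sigma=float(np.exp(-2)), theta=0.0, mu=(0.15, -0.1)),
    "argos-t": dict(gamma=0.7, sigma=float(np.exp(-2)), theta=0.3, mu=(0.0, 0.0)),
}


def make_fixture(kind: str, seed: int = 0, out_dir=".", n_obs: int = 60) -> dict:
    """Write a small deterministic telemetry CSV plus a sidecar JSON.

    ``kind`` selects the generating regime ("persistent", "tortuous",
    "drifted" or "argos-t"); the sidecar records the true parameters and the
    seed so tests and docs can check recovery.  Returns the sidecar dict
    (with file paths added).
    """
    if kind not in _FIXTURE_PARAMS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    p = _FIXTURE_PARAMS[kind]
    params = MovementParams.isotropic(p["gamma"], p["sigma"], p["theta"], p["mu"])
    times = sample_observation_times(n_obs, seed=np.random.default_rng((seed, 0)))
    path = simulate_continuous(params, times, seed=np.random.default_rng((seed, 1)))
    if kind == "argos-t":
        noise = default_argos_noise()
        rng = np.random.default_rng((seed, 2))
        labels = np.array(sorted(noise.scales), object)
        classes = labels[rng.integers(0, len(labels), n_obs)]
        obs = simulate_observations(path, noise, classes, np.random.default_rng((seed, 3)))
    else:
        noise = NoiseModel.gaussian(0.1)
        obs = simulate_observations(path, noise, seed=np.random.default_rng((seed, 3)))
    obs.track_id = kind
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{kind}.csv"
    write_telemetry(obs, csv_path)
    meta = {
        "kind": kind,
        "seed": seed,
        "n_obs": n_obs,
        "true_params": p,
        "obs_sd": 0.1 if kind != "argos-t" else None,
        "noise_kind": noise.kind,
        "csv": str(csv_path),
    }
    json_path = out_dir / f"{kind}.json"
    json_path.write_text(json.dumps(meta, indent=2))
    meta["json"] = str(json_path)
    return meta
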