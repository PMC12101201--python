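"""File formats: stereo WAV, manifest/trial/cue CSV, trajectories.

WAV files are written as float32 PCM at the working sample rate, which
round-trips losslessly.  Tables are UTF-8 CSV with unit-bearing column
names (``itd_us``, ``azimuth_deg``, ...) so units cannot drift silently.
Readers validate required columns and sample rates and raise named,
actionable errors; nothing is ever silently resampled.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cues import CueProfile
from .exceptions import MissingColumnError, SampleRateError
from .head_model import HRIRSet
from .localization import Trajectory, Trial

TRIAL_COLUMNS = [
    "listener_id",
    "condition",
    "stimulus",
    "level",
    "snr",
    "target_azimuth",
    "target_elevation",
    "response_azimuth",
    "response_elevation",
    "reaction_time",
]

CUE_COLUMNS = ["azimuth_deg", "itd_us", "ild_db", "condition", "snr_db"]

# fixed float format => byte-identical CSV output across reruns
FLOAT_FORMAT = "%.10g"


def write_wav(path, left: np.ndarray, right: np.ndarray, sample_rate: int) -> None:
    """Write a stereo float32 WAV."""
    data = np.stack([np.asarray(left), np.asarray(right)], axis=1).astype(np.float32)
    wavfile.write(str(path), int(sample_rate), data)


def read_wav(path, expected_rate: int | None = None):
    """Read a stereo WAV; returns (left, right, sample_rate).

    Raises
    ------
    SampleRateError
        If ``expected_rate`` is given and does not match; resample
        explicitly (e.g. scipy.signal.resample_poly) before retrying —
        nothing is resampled silently.
    """
    rate, data = wavfile.read(str(path))
    if expected_rate is not None and rate != expected_rate:
        raise SampleRateError(
            f"{path}: sample rate {rate} Hz, expected {expected_rate} Hz; "
            "resample the file explicitly (no silent resampling)"
        )
    if data.ndim == 1:
        data = np.stack([data, data], axis=1)
    return data[:, 0].astype(float), data[:, 1].astype(float), rate


def _check_columns(df: pd.DataFrame, required, path=None) -> None:
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(col, str(path) if path else None)


# -- HRIR sets -------------------------------------------------------------


def write_hrir_set(directory, hrirs: HRIRSet, stem: str = "hrir") -> Path:
    """Write one stereo WAV per direction plus a CSV manifest.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (az, el), (l, r) in sorted(hrirs.entries.items()):
        fname = f"{stem}_{hrirs.condition}_az{az:+06.1f}_el{el:+06.1f}.wav"
        write_wav(directory / fname, l, r, hrirs.sample_rate)
        rows.append(
            {
                "azimuth_deg": az,
                "elevation_deg": el,
                "condition": hrirs.condition,
                "snr_db": np.nan if hrirs.snr is None else hrirs.snr,
                "sample_rate": hrirs.sample_rate,
                "filename": fname,
            }
        )
    manifest = directory / f"{stem}_{hrirs.condition}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=FLOAT_FORMAT)
    return manifest


def read_hrir_set(manifest_path) -> HRIRSet:
    """Load an HRIR set from a manifest CSV written by :func:`write_hrir_set`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    _check_columns(
        df,
        ["azimuth_deg", "elevation_deg", "condition", "sample_rate", "filename"],
        manifest_path,
    )
    rate = int(df["sample_rate"].iloc[0])
    snr = df["snr_db"].iloc[0] if "snr_db" in df.columns else np.nan
    out = HRIRSet(
        sample_rate=rate,
        condition=str(df["condition"].iloc[0]),
        snr=None if pd.isna(snr) else float(snr),
    )
    for _, row in df.iterrows():
        l, r, _ = read_wav(manifest_path.parent / row["filename"], expected_rate=rate)
        out.put(float(row["azimuth_deg"]), float(row["elevation_deg"]), l, r)
    return out


# -- trial tables ----------------------------------------------------------


def trials_to_frame(trials) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "listener_id": t.listener_id,
                "condition": t.condition,
                "stimulus": t.stimulus,
                "level": t.level,
                "snr": np.nan if t.snr is None else t.snr,
                "target_azimuth": t.target_azimuth,
                "target_elevation": t.target_elevation,
                "response_azimuth": t.response_azimuth,
                "response_elevation": t.response_elevation,
                "reaction_time": np.nan if t.reaction_time is None else t.reaction_time,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    _check_columns(df, TRIAL_COLUMNS)
    out = []
    for _, row in df.iterrows():
        out.append(
            Trial(
                listener_id=str(row["listener_id"]),
                condition=str(row["condition"]),
                stimulus=str(row["stimulus"]),
                level=float(row["level"]),
                snr=None if pd.isna(row["snr"]) else float(row["snr"]),
                target_azimuth=float(row["target_azimuth"]),
                target_elevation=float(row["target_elevation"]),
                response_azimuth=float(row["response_azimuth"]),
                response_elevation=float(row["response_elevation"]),
                reaction_time=(
                    None if pd.isna(row["reaction_time"]) else float(row["reaction_time"])
                ),
            )
        )
    return out


def write_trials(path, trials) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trials(path) -> list[Trial]:
    df = pd.read_csv(path)
    _check_columns(df, TRIAL_COLUMNS, path)
    return frame_to_trials(df)


# -- cue profiles ----------------------------------------------------------


def write_cues(path, profiles) -> None:
    """Write one or more cue profiles to a single CSV."""
    if isinstance(profiles, CueProfile):
        profiles = [profiles]
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_cues(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CUE_COLUMNS, path)
    return df


# -- trajectories ----------------------------------------------------------


def write_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame(
        {
            "time_s": traj.time,
            "azimuth_deg": traj.azimuth,
            "elevation_deg": traj.elevation,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trajectory(path, tracker_rate: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    _check_columns(df, ["time_s", "azimuth_deg", "elevation_deg"], path)
    t = df["time_s"].to_numpy()
    if tracker_rate is None:
        tracker_rate = 1.0 / float(np.median(np.diff(t)))
    return Trajectory(
        time=t,
        azimuth=df["azimuth_deg"].to_numpy(),
        elevation=df["elevation_deg"].to_numpy(),
        tracker_rate=tracker_rate,
    )
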