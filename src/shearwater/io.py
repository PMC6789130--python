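"""Plain-text readers/writers for the pipeline's interchange files.

All stage interfaces are CSV (ISO-8601 UTC timestamps) or JSON so that any
stage can be replaced by external tooling.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

__all__ = [
    "read_light_csv",
    "write_light_csv",
    "read_immersion_csv",
    "write_immersion_csv",
    "read_fixes_csv",
    "write_fixes_csv",
    "read_isotopes_csv",
    "write_isotopes_csv",
]


def write_light_csv(series: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "timestamp_utc": pd.DatetimeIndex(series["timestamp"]).strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "light": np.round(series["light"].to_numpy(float), 4),
        }
    )
    out.to_csv(path, index=False)


def read_light_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df["timestamp_utc"]).to_numpy().astype("datetime64[s]"),
            "light": df["light"].astype(float),
        }
    )


def write_immersion_csv(series: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "timestamp_utc": pd.DatetimeIndex(series["timestamp"]).strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "wet_count": series["wet_count"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def read_immersion_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df["timestamp_utc"]).to_numpy().astype("datetime64[s]"),
            "wet_count": df["wet_count"].astype(int),
        }
    )


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    df["time"] = pd.to_datetime(df["time"]).to_numpy().astype("datetime64[s]")
    df["date"] = [ _dt.date.fromisoformat(d) for d in df["date"].astype(str) ]
    df["filters"] = df["filters"].fillna("")
    df["retained"] = df["retained"].astype(bool)
    return df


def write_isotopes_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_isotopes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("d15N", "d13C"):
        df[col] = df[col].astype(float)
    if "tracked" in df.columns:
        df["tracked"] = df["tracked"].astype(str).str.lower().isin(["true", "1"])
    return df
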