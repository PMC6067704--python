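"""CSV input/output for the pipeline.

Daily input layout (one file, all communities):
    community,date,temperature,deaths
with ISO-8601 dates and "NA" for missing temperatures.  Modelled series
use community,gcm,rcp,date,temperature; population files use
variant,year,population; metadata files carry one row per community.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

DAILY_COLUMNS = ["community", "date", "temperature", "deaths"]


def read_daily_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-community daily records; returns community -> DataFrame.

    Validates the header, date parsing, nonnegative integer deaths and
    uniqueness of (community, date); errors name the offending row
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    if list(df.columns) != DAILY_COLUMNS:
        raise ValueError(
            f"expected header {','.join(DAILY_COLUMNS)}, got {','.join(df.columns)}"
        )
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna())[0]) + 1
        raise ValueError(f"malformed date at row {row}: {df['date'].iloc[row - 1]!r}")
    df["date"] = dates
    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    bad = deaths.isna() | (deaths < 0) | (deaths != deaths.round())
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(
            f"deaths must be nonnegative integers; bad value at row {row}"
        )
    df["deaths"] = deaths.astype(int)
    dup = df.duplicated(subset=["community", "date"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 1
        raise ValueError(f"duplicate (community, date) at row {row}")

    out = {}
    for cid, grp in df.groupby("community", sort=True):
        grp = grp.sort_values("date").set_index("date")
        out[str(cid)] = grp[["temperature", "deaths"]]
    return out


def write_daily_csv(observed: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for cid in sorted(observed):
        f = observed[cid].reset_index()
        f.columns = ["date", "temperature", "deaths"]
        f.insert(0, "community", cid)
        frames.append(f)
    full = pd.concat(frames, ignore_index=True)
    full["date"] = full["date"].dt.strftime("%Y-%m-%d")
    full.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    if "community" not in meta.columns:
        raise ValueError("metadata file must have a 'community' column")
    return meta.set_index("community")


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.reset_index().to_csv(path, index=False, na_rep=NA_TOKEN)


def read_population_csv(path: str | Path) -> dict[str, pd.Series]:
    df = pd.read_csv(path)
    need = {"variant", "year", "population"}
    if not need.issubset(df.columns):
        raise ValueError(f"population file must have columns {sorted(need)}")
    out = {}
    for variant, grp in df.groupby("variant"):
        s = grp.sort_values("year").set_index("year")["population"].astype(float)
        s.index = s.index.astype(int)
        s.index.name = "year"
        out[str(variant)] = s
    return out


def write_population_csv(population: dict[str, pd.Series], path: str | Path) -> None:
    frames = []
    for variant in sorted(population):
        f = population[variant].rename("population").reset_index()
        f.insert(0, "variant", variant)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_modelled_csv(path: str | Path) -> dict[str, dict[tuple[str, str], pd.Series]]:
    df = pd.read_csv(path, parse_dates=["date"])
    need = {"community", "gcm", "rcp", "date", "temperature"}
    if not need.issubset(df.columns):
        raise ValueError(f"modelled file must have columns {sorted(need)}")
    out: dict[str, dict[tuple[str, str], pd.Series]] = {}
    for (cid, gcm, rcp), grp in df.groupby(["community", "gcm", "rcp"]):
        s = grp.sort_values("date").set_index("date")["temperature"].astype(float)
        out.setdefault(str(cid), {})[(str(gcm), str(rcp))] = s
    return out


def write_modelled_csv(
    modelled: dict[str, dict[tuple[str, str], pd.Series]], path: str | Path
) -> None:
    frames = []
    for cid in sorted(modelled):
        for (gcm, rcp) in sorted(modelled[cid]):
            s = modelled[cid][(gcm, rcp)]
            f = s.rename("temperature").reset_index()
            f.columns = ["date", "temperature"]
            f.insert(0, "rcp", rcp)
            f.insert(0, "gcm", gcm)
            f.insert(0, "community", cid)
            frames.append(f)
    full = pd.concat(frames, ignore_index=True)
    full["date"] = full["date"].dt.strftime("%Y-%m-%d")
    full.to_csv(path, index=False)
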