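"""CSV input/output for beat series and cohort proxy tables."""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .beat_spectral import PROXY_COLUMNS, BeatSeries, compute_proxies

__all__ = ["read_beat_csv", "proxies_from_directory", "write_proxy_table", "read_proxy_table"]

META_COLUMNS = ["age", "gender", "group"]


def read_beat_csv(path: str | os.PathLike, subject_id: str = "") -> dict[str, BeatSeries]:
    """Read one subject's beat series from CSV.

    Expected columns: ``rr_rest`` (ms), ``sap_rest`` (mmHg) and optionally
    ``rr_stand`` (ms); columns may have different lengths (trailing blanks
    are dropped per column).
    """
    df = pd.read_csv(path)
    out: dict[str, BeatSeries] = {}
    spec = {
        "rr_rest": ("RR", "rest"),
        "sap_rest": ("SAP", "rest"),
        "rr_stand": ("RR", "stand"),
    }
    for col, (kind, condition) in spec.items():
        if col in df.columns:
            vals = df[col].dropna().to_numpy(dtype=float)
            if vals.size:
                out[col] = BeatSeries(vals, kind=kind, condition=condition,
                                      subject_id=subject_id)
    for required in ("rr_rest", "sap_rest"):
        if required not in out:
            raise ValueError(f"{path}: missing required beat column {required!r}")
    return out


def proxies_from_directory(beats_dir: str | os.PathLike, meta_csv: str | os.PathLike,
                           order: int | str = 12) -> pd.DataFrame:
    """Compute the cohort proxy table from per-subject beat CSV files.

    ``meta_csv`` must list ``subject_id, age, gender, group, cuff_sap,
    cuff_dap``; each subject_id must have a matching ``<subject_id>.csv``
    in ``beats_dir``.
    """
    meta = pd.read_csv(meta_csv)
    records = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        series = read_beat_csv(Path(beats_dir) / f"{sid}.csv", subject_id=sid)
        rec = compute_proxies(
            series["rr_rest"],
            series["sap_rest"],
            series.get("rr_stand"),
            cuff_sap=float(row["cuff_sap"]),
            cuff_dap=float(row["cuff_dap"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            group=str(row["group"]),
            order=order,
        )
        records.append(rec.as_dict())
    return pd.DataFrame(records)


def write_proxy_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in PROXY_COLUMNS + META_COLUMNS + ["subject_id"] if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_proxy_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return df
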