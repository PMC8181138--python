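"""File schemas: coupon CSV, rib-strain CSV, model JSON, run manifests.

CSV dialect is locale-independent: comma-separated, ``.`` decimal, UTF-8,
header mandatory.  Engineering strains are converted to true strain on
ingest and the original convention recorded.  Probabilities in output
tables are serialized at 12 significant digits so round trips are exact at
the comparison tolerances used elsewhere.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import RIB_KEYS, RibStrainSet
from .fitting import CENSOR_CODES, coupons_to_frame
from .risk import engineering_to_true_strain

logger = logging.getLogger(__name__)

COUPON_COLUMNS = ("subject_id", "age", "sex", "failure_strain",
                  "strain_convention", "censor", "strain_rate")


class SchemaError(ValueError):
    """A file does not match its documented schema; names the row at fault."""


def read_coupons(path: str | Path) -> pd.DataFrame:
    """Read a coupon CSV, validating the schema row by row.

    Engineering strains are converted to true strain; the returned frame
    always carries true strains with ``strain_convention`` recording the
    original convention of each row.
    """
    # dtype=str stops pandas reading the 'true' convention literal as a bool
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "censor": str,
                                  "strain_convention": str})
    missing = set(COUPON_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if "strain_convention" not in df.columns:
        df["strain_convention"] = "true"
    if "censor" not in df.columns:
        df["censor"] = "exact"
    if "strain_rate" not in df.columns:
        df["strain_rate"] = 0.5

    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        if row["strain_convention"] not in ("engineering", "true"):
            raise SchemaError(f"{path}:{rowno}: unknown strain convention "
                              f"{row['strain_convention']!r}")
        if row["censor"] not in CENSOR_CODES:
            raise SchemaError(f"{path}:{rowno}: unknown censor code {row['censor']!r}")
        s = float(row["failure_strain"])
        if row["strain_convention"] == "engineering":
            if s <= -1:
                raise SchemaError(f"{path}:{rowno}: engineering strain must be > -1")
            s = engineering_to_true_strain(s)
        if s <= 0:
            raise SchemaError(f"{path}:{rowno}: failure strain must be positive")
        df.loc[idx, "failure_strain"] = s
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate subject_id {dup!r}")
    return coupons_to_frame(df)


def write_coupons(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_rib_cases(path: str | Path) -> pd.DataFrame:
    """Read a rib-strain case CSV (``case_id, occupant_age, delta_v, L1..R12``)."""
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = ({"case_id", "occupant_age"} | set(RIB_KEYS)) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for idx in df.index:
        vals = df.loc[idx, list(RIB_KEYS)].to_numpy(float)
        if np.any(vals < 0) or np.any(~np.isfinite(vals)):
            raise SchemaError(f"{path}:{idx + 2}: rib strains must be finite and >= 0")
    return df


def ribset_from_row(row: pd.Series) -> RibStrainSet:
    """Build a :class:`RibStrainSet` from one rib-strain CSV row."""
    meta = {}
    if "delta_v" in row.index and pd.notna(row["delta_v"]):
        meta["delta_v"] = float(row["delta_v"])
    return RibStrainSet(
        occupant_age=float(row["occupant_age"]),
        strains={k: float(row[k]) for k in RIB_KEYS},
        case_meta=meta,
    )


def format_probabilities(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Render probability columns at 12 significant digits (round-trip safe)."""
    out = df.copy()
    for col in columns:
        out[col] = out[col].map(lambda v: float(f"{v:.12g}"))
    return out


def write_manifest(out_dir: str | Path, command: str, inputs: dict, seed=None) -> Path:
    """Write a run manifest (inputs, seed, version, parameters) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": inputs,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
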