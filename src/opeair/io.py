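"""CSV schemas and run manifests.

All tabular interchange is UTF-8 CSV with a mandatory header row and "."
decimal separator.  The concentration-table schema is shared by the
generator, the calibration stage and the statistics layer:

    site_id, microenvironment, congener, value_ng_m3, censor

with ``censor`` one of ``detected`` / ``below_mdl`` / ``not_detected``.
Readers validate the schema and report the offending row on failure, so a
broken upstream artifact fails loudly rather than propagating.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CensorFlag
from .synthetic import TABLE_COLUMNS

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "read_edi_summary",
    "write_manifest",
    "SchemaError",
]

_CENSOR_VALUES = {f.value for f in CensorFlag}

EDI_COLUMNS = ["group", "congener", "mean", "p5", "p50", "p95"]


class SchemaError(ValueError):
    """A CSV does not match its declared schema."""


def read_concentration_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"site_id": str, "microenvironment": str, "congener": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = df[~df["censor"].isin(_CENSOR_VALUES)]
    if not bad.empty:
        raise SchemaError(
            f"{path}: row {bad.index[0] + 2}: invalid censor value "
            f"{bad.iloc[0]['censor']!r}"
        )
    values = pd.to_numeric(df["value_ng_m3"], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise SchemaError(f"{path}: row {row + 2}: non-numeric value_ng_m3")
    if (values < 0).any():
        row = int(values.index[values < 0][0])
        raise SchemaError(f"{path}: row {row + 2}: negative concentration")
    df["value_ng_m3"] = values
    dupes = df.duplicated(subset=["site_id", "congener"])
    if dupes.any():
        row = int(df.index[dupes][0])
        raise SchemaError(f"{path}: row {row + 2}: duplicate (site_id, congener) key")
    return df[TABLE_COLUMNS]


def write_concentration_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_edi_summary(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = ["group", "congener", "mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    means = pd.to_numeric(df["mean"], errors="coerce")
    if means.isna().any():
        row = int(means.index[means.isna()][0])
        raise SchemaError(f"{path}: row {row + 2}: non-numeric mean EDI")
    return df


def write_manifest(
    path: str | Path,
    *,
    command: str,
    seed: int | None,
    config_hash: str,
    record_counts: dict[str, int],
) -> None:
    """Machine-readable run manifest beside the outputs.

    Deliberately excludes wall-clock time so repeat runs with the same seed
    and config are byte-identical.
    """
    payload = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "record_counts": {k: int(v) for k, v in record_counts.items()},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def frame_records(df: pd.DataFrame) -> int:
    return int(len(df))


def round_frame(df: pd.DataFrame, ndigits: int = 6) -> pd.DataFrame:
    """Stable float formatting for byte-identical CSV output."""
    out = df.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.floating):
            out[col] = out[col].round(ndigits)
    return out
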