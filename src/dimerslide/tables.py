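"""Delimited-table readers/writers for titrations and assay traces.

Tables are UTF-8, comma- or tab-delimited, with one required header line;
units ride in the column names (``conc_nM``, ``time_s``).  Metadata —
including the resolved seed of whatever produced the table — is stored in
leading ``#key=value`` comment lines so every artifact is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .binding import Titration
from .kinetics import AssayTrace

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "write_titration",
    "read_titration",
    "write_trace",
    "read_trace",
]


class SchemaError(ValueError):
    """Table header or cells do not match the expected schema."""


def _read_meta(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            try:
                meta[key] = json.loads(val)
            except (json.JSONDecodeError, ValueError):
                meta[key] = val
    return meta, skip


def read_table(path, required: tuple[str, ...], sep: str | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Read a delimited table, validating header and numeric cells."""
    path = Path(path)
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, sep=sep, skiprows=skip, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}; "
                          f"found {list(df.columns)}")
    extra = [c for c in df.columns if c not in required and c != "replicate"]
    if extra:
        raise SchemaError(f"{path.name}: unknown columns {extra}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df[col][vals.isna()].iloc[0]
            raise SchemaError(
                f"{path.name}: non-numeric cell {bad!r} in column {col!r} "
                "(decimal commas are not accepted; use '.')")
        df[col] = vals
    return df, meta


def write_table(path, df: pd.DataFrame, meta: dict | None = None,
                sep: str = ",") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"#{key}={json.dumps(val, default=str)}\n")
        df.to_csv(fh, sep=sep, index=False)


def _conc_col(unit: str) -> str:
    return f"conc_{unit.replace('µ', 'u')}"


def write_titration(path, titration: Titration) -> None:
    data = {_conc_col(titration.unit): titration.protein_conc,
            "response": titration.response}
    if titration.replicate_id is not None:
        data["replicate"] = titration.replicate_id
    meta = {"ligand_conc": titration.ligand_conc, "unit": titration.unit}
    meta.update({k: v for k, v in titration.meta.items()
                 if isinstance(v, (str, int, float, bool, dict, list))})
    write_table(path, pd.DataFrame(data), meta)


def read_titration(path) -> Titration:
    path = Path(path)
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip, engine="python")
    conc_cols = [c for c in df.columns if c.startswith("conc_")]
    if len(conc_cols) != 1 or "response" not in df.columns:
        raise SchemaError(f"{path.name}: expected one conc_<unit> column "
                          "and a response column")
    col = conc_cols[0]
    for c in (col, "response"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"{path.name}: non-numeric cell in {c!r} "
                              "(decimal commas are not accepted; use '.')")
        df[c] = vals
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    ligand = meta.pop("ligand_conc", None)
    unit = meta.pop("unit", col.removeprefix("conc_"))
    return Titration(df[col].to_numpy(), df["response"].to_numpy(),
                     ligand_conc=ligand, unit=unit, replicate_id=rep,
                     meta=meta)


def write_trace(path, trace: AssayTrace) -> None:
    meta = {"kind": trace.kind, "scale_factor": trace.scale_factor}
    meta.update({k: v for k, v in trace.meta.items()
                 if isinstance(v, (str, int, float, bool))})
    write_table(path, pd.DataFrame({"time_s": trace.time,
                                    "signal_FU": trace.signal}), meta)


def read_trace(path) -> AssayTrace:
    df, meta = read_table(path, ("time_s", "signal_FU"))
    kind = meta.pop("kind", "sliding_fret")
    scale = float(meta.pop("scale_factor", 1.0))
    return AssayTrace(df["time_s"].to_numpy(), df["signal_FU"].to_numpy(),
                      kind=kind, meta=meta, scale_factor=scale)
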