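"""Long-format dataset I/O and run provenance.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header row
``ID,TIME,AMT,DUR,DV,MDV,AGE,WT,SEX,ARM``.  Dose rows carry AMT>0 and an
empty DV with MDV=1; observation rows carry AMT=0 and DV=score (empty DV
with MDV=1 marks a missed visit).  Lines starting with ``#`` before the
header hold provenance metadata (package version, seed, config hash).
"""

from __future__ import annotations

import io
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .params import config_hash
from .trial import TrialDataset

__all__ = ["read_dataset", "write_dataset", "provenance", "SchemaError"]

COLUMNS = ["ID", "TIME", "AMT", "DUR", "DV", "MDV", "AGE", "WT", "SEX", "ARM"]
_NUMERIC = ["ID", "TIME", "AMT", "DUR", "MDV", "AGE", "WT"]


class SchemaError(ValueError):
    """Raised when a dataset file violates the expected schema."""


def provenance(seed=None, config=None) -> dict:
    """Metadata block attached to every artifact the package writes."""
    try:
        ver = version("serinepkpd")
    except PackageNotFoundError:  # pragma: no cover - running from a tree
        ver = "unknown"
    meta = {"package": "serinepkpd", "version": ver}
    if seed is not None:
        meta["seed"] = int(seed)
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return meta


def write_dataset(dataset: TrialDataset, path: str | Path, meta: dict | None = None) -> None:
    """Serialise a trial dataset to the long CSV format."""
    demog = dataset.demographics.set_index("id")
    rows = []
    for r in dataset.doses.itertuples(index=False):
        rows.append((r.id, r.time, r.amount_mg, r.duration, "", 1))
    for r in dataset.observations.itertuples(index=False):
        dv = "" if r.missing else r.score
        rows.append((r.id, r.time, 0.0, 0.0, dv, 1 if r.missing else 0))
    table = pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "DUR", "DV", "MDV"])
    table = table.sort_values(["ID", "TIME", "MDV"], kind="stable")
    table["AGE"] = demog.loc[table["ID"], "age"].to_numpy()
    table["WT"] = demog.loc[table["ID"], "weight"].to_numpy()
    table["SEX"] = demog.loc[table["ID"], "sex"].to_numpy()
    table["ARM"] = demog.loc[table["ID"], "arm"].to_numpy()
    buf = io.StringIO()
    for key, val in (meta or provenance()).items():
        buf.write(f"# {key}: {val}\n")
    table.to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def _fail(row, col, msg) -> None:
    raise SchemaError(f"row {row}, column {col}: {msg}")


def read_dataset(path: str | Path) -> TrialDataset:
    """Read and validate a long CSV, returning a typed :class:`TrialDataset`.

    Schema violations raise :class:`SchemaError` naming the offending row
    (1-based, excluding header/comments) and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    parsed = {}
    for col in _NUMERIC:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (raw[col].str.strip() == "")
        if bad.any():
            _fail(int(bad.idxmax()) + 1, col, f"non-numeric value {raw[col][bad.idxmax()]!r}")
        parsed[col] = vals
    dv = pd.to_numeric(raw["DV"].replace("", np.nan), errors="coerce")
    has_dv = raw["DV"].str.strip() != ""
    bad_dv = has_dv & dv.isna()
    if bad_dv.any():
        _fail(int(bad_dv.idxmax()) + 1, "DV", f"non-numeric value {raw['DV'][bad_dv.idxmax()]!r}")
    mdv = parsed["MDV"].astype(int)
    inconsistent = (mdv == 0) & ~has_dv
    if inconsistent.any():
        _fail(int(inconsistent.idxmax()) + 1, "DV", "MDV=0 row with empty DV")

    df = pd.DataFrame(parsed)
    df["DV"] = dv
    df["MDV"] = mdv
    df["SEX"] = raw["SEX"]
    df["ARM"] = raw["ARM"]

    # demographic covariates must be constant within subject
    for col in ("AGE", "WT", "SEX", "ARM"):
        per_id = df.groupby("ID")[col].nunique()
        if (per_id > 1).any():
            sid = per_id[per_id > 1].index[0]
            _fail("-", col, f"subject {sid:g} has inconsistent {col} values")

    demog = (
        df.groupby("ID")
        .first()[["AGE", "WT", "SEX", "ARM"]]
        .reset_index()
        .rename(columns={"ID": "id", "AGE": "age", "WT": "weight", "SEX": "sex", "ARM": "arm"})
    )
    demog["id"] = demog["id"].astype(int)
    is_dose = df["AMT"] > 0
    doses = df[is_dose][["ID", "TIME", "AMT", "DUR"]].rename(
        columns={"ID": "id", "TIME": "time", "AMT": "amount_mg", "DUR": "duration"}
    )
    doses["id"] = doses["id"].astype(int)
    obs = df[~is_dose][["ID", "TIME", "DV", "MDV"]].rename(
        columns={"ID": "id", "TIME": "time", "DV": "score"}
    )
    obs["missing"] = obs.pop("MDV").astype(bool)
    obs["id"] = obs["id"].astype(int)
    try:
        return TrialDataset(
            demographics=demog.reset_index(drop=True),
            doses=doses.reset_index(drop=True),
            observations=obs.reset_index(drop=True),
        )
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> None:
    """Write a JSON artifact with a standard metadata block."""
    out = {"meta": meta or provenance(), **obj}
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
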