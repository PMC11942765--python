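"""Readers and writers for the package's plain-text formats.

Formats: SMILES lists (``id<TAB>smiles``), descriptor CSV (one row per
polymer, Table-style feature columns), Tg tables (Celsius; multiple
measurements for one polymer may be given semicolon-separated and are
averaged), model JSON, report JSON and consensus CSV.  All CSV output is
comma-separated UTF-8 with ``.`` decimals and a mandatory header; output
files embed the seed/config that produced them in a metadata block
(``#``-prefixed comment lines for CSV, a ``config`` key for JSON) so every
artifact records its provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .correlations import CorrelationReport, FeatureTable
from .descriptors import FEATURE_NAMES
from .errors import SchemaError

logger = logging.getLogger(__name__)

TG_ALIASES = ("Tg", "tg", "Tg_C", "tg_c")


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read ``id<TAB>smiles`` records; blank lines and ``#`` comments skipped."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(
                f"{path}:{ln}: expected 'id<TAB>smiles', got {line!r}"
            )
        pid, smi = parts[0].strip(), parts[1].strip()
        if pid in seen:
            raise SchemaError(f"{path}:{ln}: duplicate id {pid!r}")
        seen.add(pid)
        out.append((pid, smi))
    return out


def _parse_tg_cell(value, pid: str) -> float:
    """One Tg cell: a number, or semicolon-separated numbers whose mean is
    stored (the convention for multi-source measurements)."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if np.isnan(value):
            raise SchemaError(f"row {pid!r}: missing Tg value")
        return float(value)
    text = str(value).strip()
    parts = [p for p in text.split(";") if p.strip()]
    try:
        vals = [float(p) for p in parts]
    except ValueError:
        raise SchemaError(f"row {pid!r}: non-numeric Tg value {value!r}")
    if not vals:
        raise SchemaError(f"row {pid!r}: empty Tg value")
    if len(vals) > 1:
        logger.info(
            "polymer %s: %d Tg values spanning %.1f..%.1f C, storing mean %.1f",
            pid, len(vals), min(vals), max(vals), float(np.mean(vals)),
        )
    return float(np.mean(vals))


def read_polymer_table(
    path: str | Path, require_tg: bool = False
) -> pd.DataFrame:
    """Read a polymer CSV with columns ``id`` (+ optional ``smiles``,
    descriptor columns, and a Tg column in Celsius).

    Semicolon-separated Tg entries are averaged.  Duplicate ids and
    non-numeric Tg raise :class:`SchemaError` naming the offending row.
    """
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'id'")
    df["id"] = df["id"].astype(str)
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate ids {dupes}")
    tg_col = next((c for c in TG_ALIASES if c in df.columns), None)
    if tg_col is None and require_tg:
        raise SchemaError(f"{path}: no Tg column (expected one of {TG_ALIASES})")
    if tg_col is not None:
        df["Tg"] = [
            _parse_tg_cell(v, pid) for v, pid in zip(df[tg_col], df["id"])
        ]
        if tg_col != "Tg":
            df = df.drop(columns=[tg_col])
    return df


def feature_table_from_frame(df: pd.DataFrame) -> FeatureTable:
    """Build a FeatureTable from a polymer frame, using whichever feature
    columns are present (all numeric non-id/smiles/Tg columns)."""
    skip = {"id", "smiles", "Tg"}
    feat_cols = [c for c in df.columns if c not in skip]
    known = [c for c in FEATURE_NAMES if c in feat_cols]
    cols = known if known else feat_cols
    X = df[cols].apply(pd.to_numeric)
    tg = df["Tg"] if "Tg" in df.columns else None
    return FeatureTable(
        ids=df["id"].tolist(),
        X=X.reset_index(drop=True),
        tg=None if tg is None else tg.reset_index(drop=True).astype(float),
    )


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def write_descriptor_csv(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Descriptor table with deterministic column order
    (id, smiles, then the canonical feature order)."""
    lead = [c for c in ("id", "smiles") if c in df.columns]
    feats = [c for c in FEATURE_NAMES if c in df.columns]
    rest = [c for c in df.columns if c not in lead + feats]
    ordered = df[lead + feats + rest]
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        ordered.to_csv(fh, index=False)


def write_csv(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report_json(
    report: CorrelationReport, path: str | Path, metadata: dict | None = None
) -> None:
    doc = {
        "config": metadata or {},
        "pairwise": _jsonable(report.pairwise),
        "vip": _jsonable(report.vip),
        "loading_cone_members": report.loading_cone_members,
        "rf_importance": _jsonable(report.rf_importance),
        "pc_variances_without_tg": _jsonable(report.pc_variances_without_tg),
        "pc_variances_with_tg": _jsonable(report.pc_variances_with_tg),
        "cluster_profiles": [
            {
                "label": p.label,
                "mean_tg": p.mean_tg,
                "sd_tg": p.sd_tg,
                "member_ids": p.member_ids,
            }
            for p in report.cluster_profiles
        ],
        "consensus": [
            {
                "feature": r.feature,
                "times_selected": r.times_selected,
                "correlation": r.correlation_sign,
            }
            for r in report.consensus
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
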