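"""Readers and writers for screen tables.

All tables are plain TSV with header-name-based (order-free) column
resolution; supplementary spreadsheets in XLSX layout are read through
pandas/openpyxl with a configurable header map.  Rows with non-numeric
signal values are rejected, counted, and logged rather than aborting the
read.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from .epistasis import EPISTASIS_ASSAYS

log = logging.getLogger(__name__)

WELL_REQUIRED = ("plate", "well", "reagent_id", "role", "assay", "signal")
KNOWN_ROLES = {"sample", "neg_ctrl", "pos_ctrl_down", "pos_ctrl_up"}


def _require_columns(frame: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} missing required column(s): {missing}")


def read_well_table(path) -> pd.DataFrame:
    """Read a well-level screen table (TSV).

    Required columns: ``plate, well, reagent_id, role, assay, signal``
    (``cells`` and ``replicate`` optional).  Rows whose signal is not
    numeric are dropped; their count is logged and recorded in
    ``frame.attrs["n_rejected"]``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, WELL_REQUIRED, f"well table {path}")
    signal = pd.to_numeric(frame["signal"], errors="coerce")
    bad = signal.isna()
    if bad.any():
        log.warning("%s: rejecting %d row(s) with non-numeric signal", path, int(bad.sum()))
    frame = frame[~bad].copy()
    frame["signal"] = signal[~bad]
    unknown_roles = set(frame["role"].unique()) - KNOWN_ROLES
    if unknown_roles:
        raise ValueError(f"{path}: unknown role value(s) {sorted(unknown_roles)}")
    for col in ("cells", "replicate"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce").astype("Int64")
    frame = frame.reset_index(drop=True)
    frame.attrs["n_rejected"] = int(bad.sum())
    return frame


def write_table(frame: pd.DataFrame, path, index: bool = False):
    """Write a TSV with a stable float format (deterministic output)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_profile_table(path, gene_column: str = "gene") -> pd.DataFrame:
    """Read a genes x assays profile table (TSV) indexed by gene id."""
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, [gene_column], f"profile table {path}")
    frame = frame.set_index(gene_column)
    return frame.apply(pd.to_numeric, errors="coerce")


#: Default logical -> header map for the epistasis supplementary layout:
#: gene symbol column plus the six screen columns named by screen number.
S3_DEFAULT_MAP = {
    "gene": "gene",
    **{assay: f"screen_{i + 1}" for i, assay in enumerate(EPISTASIS_ASSAYS)},
    "r_ras_raf": "r_ras_raf",
    "r_raf_mek": "r_raf_mek",
    "r_mek_mapk": "r_mek_mapk",
    "interval": "interval",
    "confidence": "confidence",
}


def read_supplementary_s3(
    path,
    header_map: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an epistasis-screen supplementary table (XLSX or TSV).

    The table holds, per candidate gene, the six log10-transformed
    normalized pMAPK screen values, and usually also the reported
    correlations, interval call, and confidence score.

    Parameters
    ----------
    header_map : mapping from logical names (``gene``, the six assay
        names, ``r_ras_raf`` ... ``confidence``) to the file's actual
        column headers; merged over :data:`S3_DEFAULT_MAP`.  Header
        matching is case-insensitive.
    sheet : sheet name or index for XLSX input.

    Returns
    -------
    (profiles, reported)
        ``profiles``: genes x six assay columns (log10 values), indexed
        by gene.  ``reported``: whatever of the reported call columns
        were present (possibly empty).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        frame = pd.read_csv(path, sep="\t")
    mapping = dict(S3_DEFAULT_MAP)
    if header_map:
        mapping.update(header_map)
    lower = {str(c).strip().lower(): c for c in frame.columns}

    def resolve(logical, required):
        header = mapping[logical]
        col = lower.get(str(header).strip().lower())
        if col is None and required:
            raise ValueError(f"{path}: cannot resolve column {header!r} for {logical!r}")
        return col

    gene_col = resolve("gene", required=True)
    assay_cols = {a: resolve(a, required=True) for a in EPISTASIS_ASSAYS}
    profiles = frame[[gene_col] + [assay_cols[a] for a in EPISTASIS_ASSAYS]].copy()
    profiles.columns = ["gene"] + list(EPISTASIS_ASSAYS)
    profiles = profiles.set_index("gene")
    profiles = profiles.apply(pd.to_numeric, errors="coerce")

    reported_cols = {}
    for logical in ("r_ras_raf", "r_raf_mek", "r_mek_mapk", "interval", "confidence"):
        col = resolve(logical, required=False)
        if col is not None:
            reported_cols[logical] = col
    reported = frame[[gene_col] + list(reported_cols.values())].copy()
    reported.columns = ["gene"] + list(reported_cols.keys())
    reported = reported.set_index("gene")
    return profiles, reported


def read_config(path) -> dict:
    """Read a YAML pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
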