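"""Tabular I/O for the pipeline: evidence, protein groups, results.

All tables are UTF-8 tab-separated text with a ``.`` decimal separator.
The native schema is the single source of truth; the ``maxquant``
dialect of :func:`read_evidence` is a documented column-name mapping
onto it, so the pipeline is insulated from upstream tool drift.

Native evidence columns
-----------------------
protein_id, peptide_sequence, lysine_count, charge, fraction_id,
mouse_id, cohort, intensity_light, intensity_mixed, intensity_heavy,
n_observations.

For single-lysine peptides ``intensity_heavy`` is the fully labeled
(K6) species and ``intensity_mixed`` is zero.  For double-lysine
peptides the three columns hold the LL / HL / HH isotopologues; the HL
species exists only in the native schema (the MaxQuant dialect maps it
to zero) and feeds the precursor-pool estimator.

Native protein-group columns
----------------------------
protein_id, fraction_id, mouse_id, cohort, abundance — one row per
(protein, fraction, mouse).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "K6_MASS_SHIFT",
    "k6_mass_shift",
    "read_evidence",
    "read_protein_groups",
    "read_sample_map",
    "write_results",
    "validate_table",
    "EVIDENCE_COLUMNS",
    "PROTEIN_GROUP_COLUMNS",
    "SAMPLE_MAP_COLUMNS",
]

#: Exact mass difference (Da) between six 13C and six 12C atoms, i.e.
#: between a K6 and a K0 lysine: 6 x (13.00335483507 - 12).
K6_MASS_SHIFT = 6 * (13.00335483507 - 12.0)

EVIDENCE_COLUMNS = [
    "protein_id",
    "peptide_sequence",
    "lysine_count",
    "charge",
    "fraction_id",
    "mouse_id",
    "cohort",
    "intensity_light",
    "intensity_mixed",
    "intensity_heavy",
    "n_observations",
]
_EVIDENCE_REQUIRED = [
    "protein_id",
    "lysine_count",
    "charge",
    "fraction_id",
    "mouse_id",
    "cohort",
    "intensity_light",
    "intensity_heavy",
    "n_observations",
]

PROTEIN_GROUP_COLUMNS = ["protein_id", "fraction_id", "mouse_id", "cohort", "abundance"]
SAMPLE_MAP_COLUMNS = ["raw_file", "fraction_id", "mouse_id", "cohort"]

#: MaxQuant evidence.txt dialect -> native column names.  Sample identity
#: (fraction/mouse/cohort) comes from a companion sample map keyed on
#: "Raw file"; the HL isotopologue of 2-K peptides is not exported by
#: the upstream tool, so intensity_mixed is zero in this dialect.
MAXQUANT_COLUMN_MAP = {
    "Proteins": "protein_id",
    "Sequence": "peptide_sequence",
    "K Count": "lysine_count",
    "Charge": "charge",
    "Raw file": "raw_file",
    "Intensity L": "intensity_light",
    "Intensity H": "intensity_heavy",
    "Ratio H/L count": "n_observations",
}

COHORTS = ("control", "disease")


class SchemaError(ValueError):
    """An input table does not match its declared column schema."""


def k6_mass_shift(n_labeled_lysines: int, charge: int) -> float:
    """m/z spacing (Da) of a K0/K6 peptide ion pair.

    ``n_labeled_lysines`` heavy lysines shift the peptide mass by
    n x 6.020129 Da, observed divided by the charge state: 6.02 Da at
    z=1, 3.01 Da at z=2 for a single labeled lysine.
    """
    if int(n_labeled_lysines) != n_labeled_lysines or n_labeled_lysines < 1:
        raise ValueError("n_labeled_lysines must be a positive integer")
    if int(charge) != charge or charge < 1:
        raise ValueError("charge must be a positive integer")
    return n_labeled_lysines * K6_MASS_SHIFT / charge


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty: no header or rows") from None
    if df.empty and len(df.columns) == 0:
        raise SchemaError(f"{path} is empty: no header or rows")
    return df

def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Read a raw-file -> (fraction, mouse, cohort) sample map."""
    df = _read_tsv(path)
    _require(df, SAMPLE_MAP_COLUMNS, path)
    bad = ~df["cohort"].isin(COHORTS)
    if bad.any():
        raise SchemaError(
            f"{path}: cohort must be one of {COHORTS}, got {sorted(df.loc[bad, 'cohort'].unique())}"
        )
    return df[SAMPLE_MAP_COLUMNS]


def read_evidence(
    path: str | Path,
    dialect: str = "native",
    sample_map: str | Path | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a peptide evidence table.

    ``dialect`` is ``"native"`` or ``"maxquant"``.  The MaxQuant dialect
    requires a sample map to resolve raw files to fraction, mouse and
    cohort.  Rows with zero total intensity, unparseable numeric fields,
    or a lysine count disagreeing with the sequence are dropped with a
    logged count.  Returns a frame with the native columns.
    """
    if dialect not in ("native", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    if dialect == "maxquant":
        required = [c for c in MAXQUANT_COLUMN_MAP if c != "K Count"]
        _require(df, required, path)
        df = df.rename(columns=MAXQUANT_COLUMN_MAP)
        if "lysine_count" not in df.columns:
            df["lysine_count"] = df["peptide_sequence"].str.count("K").astype(str)
        df["intensity_mixed"] = "0"
        if sample_map is None:
            raise SchemaError("maxquant dialect requires a sample map")
    if sample_map is not None:
        smap = (
            sample_map
            if isinstance(sample_map, pd.DataFrame)
            else read_sample_map(sample_map)
        )
        if "raw_file" not in df.columns:
            raise SchemaError(f"{path}: sample map given but no raw_file column")
        df = df.drop(columns=[c for c in ("fraction_id", "mouse_id", "cohort") if c in df], errors="ignore")
        df = df.merge(smap, on="raw_file", how="left")
        unmapped = df["mouse_id"].isna()
        if unmapped.any():
            raise SchemaError(
                f"{path}: {int(unmapped.sum())} rows reference raw files absent from the sample map"
            )
        df = df.drop(columns=["raw_file"])
    if "intensity_mixed" not in df.columns:
        df["intensity_mixed"] = "0"
    if "peptide_sequence" not in df.columns:
        df["peptide_sequence"] = ""
    _require(df, _EVIDENCE_REQUIRED, path)
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")

    n_in = len(df)
    num_cols = [
        "lysine_count",
        "charge",
        "intensity_light",
        "intensity_mixed",
        "intensity_heavy",
        "n_observations",
    ]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=num_cols)
    total = df["intensity_light"] + df["intensity_mixed"] + df["intensity_heavy"]
    df = df[total > 0]
    has_seq = df["peptide_sequence"].fillna("").str.len() > 0
    seq_k = df["peptide_sequence"].fillna("").str.count("K")
    df = df[~has_seq | (seq_k == df["lysine_count"])]
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise SchemaError(
            f"{path}: cohort must be one of {COHORTS}, got {sorted(df.loc[bad_cohort, 'cohort'].unique())}"
        )
    dropped = n_in - len(df)
    if dropped:
        logger.info("read_evidence(%s): dropped %d of %d rows failing validation", path, dropped, n_in)
    if df.empty:
        raise SchemaError(f"{path}: no valid rows after validation")
    for c in ("lysine_count", "charge", "n_observations"):
        df[c] = df[c].astype(int)
    return df[EVIDENCE_COLUMNS].reset_index(drop=True)


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a per-fraction protein abundance (protein-group) table."""
    df = _read_tsv(path)
    _require(df, PROTEIN_GROUP_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    n_in = len(df)
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")
    df = df.dropna(subset=["abundance"])
    df = df[df["abundance"] >= 0]
    dropped = n_in - len(df)
    if dropped:
        logger.info("read_protein_groups(%s): dropped %d invalid rows", path, dropped)
    key = ["protein_id", "fraction_id", "mouse_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise SchemaError(
            f"{path}: {int(dup.sum())} duplicate (protein, fraction, mouse) records"
        )
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise SchemaError(f"{path}: cohort must be one of {COHORTS}")
    return df[PROTEIN_GROUP_COLUMNS].reset_index(drop=True)


def write_results(
    records: pd.DataFrame,
    path: str | Path,
    *,
    allow_empty: bool = False,
    header: dict | None = None,
    float_precision: int = 8,
) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``protein_id`` (then by any other key-like
    columns present), floats are serialized at a fixed precision, and an
    optional provenance header is emitted as ``# key: value`` comment
    lines, so identical inputs always produce byte-identical files.
    """
    if records.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path} (pass allow_empty=True)")
    path = Path(path)
    df = records.copy()
    sort_cols = [
        c
        for c in ("protein_id", "fraction_id", "cohort", "mouse_id", "peptide_sequence", "age_days")
        if c in df.columns
    ]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    lines = []
    if header:
        for key in sorted(header):
            lines.append(f"# {key}: {header[key]}")
    body = df.to_csv(sep="\t", index=False, float_format=f"%.{float_precision}g")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body, encoding="utf-8")


def validate_table(path: str | Path, kind: str) -> dict:
    """Validate an input table against its schema; returns a report dict."""
    readers = {
        "evidence": lambda p: read_evidence(p, dialect="native"),
        "protein-groups": read_protein_groups,
        "sample-map": read_sample_map,
    }
    if kind not in readers:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(readers)}")
    try:
        df = readers[kind](path)
    except (SchemaError, FileNotFoundError) as exc:
        return {"path": str(path), "kind": kind, "valid": False, "error": str(exc)}
    return {
        "path": str(path),
        "kind": kind,
        "valid": True,
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
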