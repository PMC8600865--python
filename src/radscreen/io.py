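"""Readers and writers for the tab-separated formats the pipeline touches.

Expression matrices are genes x samples (first column the gene id, header row
the sample ids).  Clinical tables are samples x variables and are validated
against a declared ClinicalSchema.  Missingness markers follow TCGA export
conventions; values written and read back round-trip exactly.
"""

from __future__ import annotations

import logging
import math
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .config import MISSING_MARKERS, ClinicalSchema

if TYPE_CHECKING:  # pragma: no cover
    from .discovery import RSGeneCall

logger = logging.getLogger(__name__)

SCENARIOS = ("A", "B", "C", "D")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed file whose content violates the declared schema."""


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Duplicate gene rows are collapsed by keeping the first occurrence (with a
    warning); any non-numeric cell is a parse error naming its location.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"duplicate sample ids in header of {path}: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed structure
        raise ParseError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("duplicate gene ids %s in %s: keeping first occurrence", dups, path)
        df = df[~df.index.duplicated(keep="first")]
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric expression cell at gene {gene!r}, sample {col!r} "
                f"in {path}: {df.loc[gene, col]!r}"
            )
        values[col] = converted.to_numpy(dtype=float)
    values.index.name = df.index.name or "gene"
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene")


def read_clinical(path, schema: ClinicalSchema) -> pd.DataFrame:
    """Read and validate a clinical table.

    Missing markers ("", "NA", "NaN", "[Not Available]", "[Discrepancy]") map
    to missing values; categorical levels are checked against the schema's
    declared reference (which must be among the observed levels when any are
    observed); os_event outside {0, 1} is a validation error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot parse clinical table {path}: {exc}") from exc
    if schema.sample_col not in df.columns:
        raise ParseError(f"clinical table {path} lacks a {schema.sample_col!r} column")
    if df[schema.sample_col].duplicated().any():
        raise ValidationError(f"duplicate sample ids in {path}")
    df = df.set_index(schema.sample_col)

    marker_hits = df.isin([m for m in MISSING_MARKERS if m != ""]).to_numpy().sum()
    if marker_hits:
        logger.info("%d cells matched a missing-value marker in %s", marker_hits, path)
    df = df.replace(list(MISSING_MARKERS), np.nan)

    out = pd.DataFrame(index=df.index)
    for col, kind in ((schema.time_col, "time"), (schema.event_col, "event"), (schema.rt_col, "binary")):
        if col not in df.columns:
            raise ParseError(f"clinical table {path} lacks required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            raise ParseError(f"non-numeric value in column {col!r} at sample {df.index[bad][0]!r}")
        if kind == "time":
            if (vals.dropna() <= 0).any():
                raise ValidationError(f"non-positive {col} in {path}")
        else:
            outside = vals.dropna()[~vals.dropna().isin([0, 1])]
            if len(outside):
                raise ValidationError(
                    f"{col} must be 0/1; sample {outside.index[0]!r} has {outside.iloc[0]!r}"
                )
        out[col] = vals.astype(float)
    for cov in schema.covariates:
        if cov.name not in df.columns:
            raise ParseError(f"clinical table {path} lacks declared covariate {cov.name!r}")
        if cov.kind == "continuous":
            vals = pd.to_numeric(df[cov.name], errors="coerce")
            bad = df[cov.name].notna() & vals.isna()
            if bad.any():
                raise ParseError(
                    f"non-numeric value in continuous covariate {cov.name!r} "
                    f"at sample {df.index[bad][0]!r}"
                )
            out[cov.name] = vals.astype(float)
        else:
            observed = df[cov.name].dropna().astype(str)
            levels = set(observed.unique())
            if levels and str(cov.reference) not in levels:
                raise ValidationError(
                    f"reference level {cov.reference!r} of {cov.name!r} not among "
                    f"observed levels {sorted(levels)}"
                )
            out[cov.name] = df[cov.name].astype(object)
    return out


def write_clinical(clin: pd.DataFrame, path, schema: ClinicalSchema) -> None:
    df = clin.copy()
    for col in (schema.event_col, schema.rt_col):
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index_label=schema.sample_col, na_rep="NA")


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_rs_table(calls: Iterable["RSGeneCall"], path) -> None:
    """Write one row per gene: verdict, type, direction and the four
    scenario statistics, tab-separated."""
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to write")
    header = ["gene", "is_rs", "type", "direction", "ambiguous"]
    for s in SCENARIOS:
        header += [f"{s}_holds", f"{s}_hr", f"{s}_ci_lower", f"{s}_ci_upper", f"{s}_p"]
    lines = ["\t".join(header)]
    for call in calls:
        row = [
            call.gene_id,
            str(int(call.is_rs)),
            call.rs_type,
            call.direction,
            str(int(call.ambiguous)),
        ]
        for s in SCENARIOS:
            res = call.panel.scenarios[s]
            row += [str(int(res.holds)), _fmt(res.hr), _fmt(res.ci_lower), _fmt(res.ci_upper), _fmt(res.p)]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_rs_table(path) -> pd.DataFrame:
    """Read back a written RS-call table (audit / intersection input)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("is_rs", "ambiguous") + tuple(f"{s}_holds" for s in SCENARIOS):
        df[col] = df[col].astype(int).astype(bool)
    return df
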