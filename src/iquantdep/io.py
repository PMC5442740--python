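"""TSV / GMT readers and writers for the pipeline's tables.

All tables travel as plain UTF-8 TSV with LF line endings and a header
row; gene sets use the standard GMT dialect
(``set_name<TAB>description<TAB>member1<TAB>member2...``).  Readers
validate structure and report malformed lines with their line numbers;
writer/reader pairs round-trip losslessly on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection

PSM_COLUMNS = [
    "psm_id",
    "peptide",
    "protein",
    "is_decoy",
    "score",
    "replicate",
    "i114",
    "i115",
    "i116",
    "i117",
]

TRUTH_COLUMNS = [
    "protein_id",
    "true_log2fc_1day",
    "true_log2fc_2month",
    "is_dep_1day",
    "is_dep_2month",
    "cell_type_membership",
]

PROTEIN_RATIO_COLUMNS = [
    "protein",
    "replicate",
    "log2_abundance_1day",
    "log2_abundance_2month",
    "n_nonredundant_peptides",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _check_no_delimiters(values, what: str) -> None:
    bad = [v for v in values if "\t" in str(v) or "\n" in str(v)]
    if bad:
        raise FormatError(
            f"{what} contains tab/newline characters and cannot be written "
            f"as TSV: {bad[:3]!r}"
        )


def _write_tsv(df: pd.DataFrame, path, str_cols) -> None:
    for col in str_cols:
        _check_no_delimiters(df[col], f"column {col!r}")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_psm_tsv(psms: pd.DataFrame, path) -> None:
    extra = [c for c in psms.columns if c not in PSM_COLUMNS]
    _write_tsv(psms[PSM_COLUMNS + extra], path, ["psm_id", "peptide", "protein"])


def read_psm_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "peptide": str, "protein": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing PSM columns {missing}")
    for col in ("score", "i114", "i115", "i116", "i117"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna())
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at data line "
                f"{bad[0] + 2}"
            )
        df[col] = vals
    if (df[["i114", "i115", "i116", "i117"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative reporter intensities")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the simulator's planted ground truth as TSV."""
    if truth.empty and list(truth.columns) != TRUTH_COLUMNS:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    _write_tsv(truth[TRUTH_COLUMNS], path, ["protein_id", "cell_type_membership"])


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing truth columns {missing}")
    df["is_dep_1day"] = df["is_dep_1day"].astype(bool)
    df["is_dep_2month"] = df["is_dep_2month"].astype(bool)
    return df


def write_protein_ratios(ratios: pd.DataFrame, path) -> None:
    _write_tsv(ratios[PROTEIN_RATIO_COLUMNS], path, ["protein"])


def read_protein_ratios(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    missing = [c for c in PROTEIN_RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing protein ratio columns {missing}")
    return df


def write_dep_table(deps: pd.DataFrame, path) -> None:
    _write_tsv(deps, path, ["protein"])


def read_dep_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    for col in ("is_dep_1day", "is_dep_2month", "is_dep_2m_over_1d"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing DEP column {col!r}")
        df[col] = df[col].astype(bool)
    return df


def write_enrichment(results: pd.DataFrame, path) -> None:
    _write_tsv(results, path, ["set_name"])


def write_gmt(collection: GeneSetCollection, path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for name in sorted(collection.sets):
        members = sorted(collection.sets[name])
        _check_no_delimiters([name] + members, f"gene set {name!r}")
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc] + members))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT gene-set file.

    ``universe`` defaults to the union of all set members; pass an explicit
    collection-wide background to override.
    """
    sets: dict[str, set[str]] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = set(members)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
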