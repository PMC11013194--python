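"""Readers and writers for the pipeline's plain-text formats.

Count and function tables are TSV with features/functions as rows and
samples as columns (first column the feature ID); intakes and sample
metadata are CSV; phylogenies are Newick; gene sets are GMT or a
three-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dii import IntakeTable
from .functions import FunctionTable, GeneSet
from .prep import CountTable

__all__ = [
    "read_intake_csv",
    "read_count_tsv",
    "read_metadata_csv",
    "read_taxonomy_tsv",
    "read_function_tsv",
    "read_gene_sets",
    "read_alias_yaml",
]

RESERVED_INTAKE_COLS = ("subject_id", "energy_kcal", "ffq_type")


def read_intake_csv(path, ffq_type: str | None = None) -> IntakeTable:
    """Read a subject x parameter intake CSV.

    Expects ``subject_id`` and ``energy_kcal`` columns; an optional
    ``ffq_type`` column (or the ``ffq_type`` argument) records the
    instrument.  All remaining columns are food parameters.
    """
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns or "energy_kcal" not in frame.columns:
        raise ValueError(f"{path}: need subject_id and energy_kcal columns")
    frame = frame.set_index("subject_id")
    ffq = None
    if "ffq_type" in frame.columns:
        ffq = frame.pop("ffq_type")
    elif ffq_type is not None:
        ffq = pd.Series(ffq_type, index=frame.index)
    energy = frame.pop("energy_kcal")
    return IntakeTable(values=frame, energy_kcal=energy, ffq_type=ffq)


def read_metadata_csv(path) -> pd.DataFrame:
    """Sample metadata CSV; requires sample_id and role columns."""
    meta = pd.read_csv(path)
    for col in ("sample_id", "role"):
        if col not in meta.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return meta.set_index("sample_id")


def read_count_tsv(path, metadata: pd.DataFrame | None = None) -> CountTable:
    """Feature x sample TSV -> CountTable (samples as rows).

    Roles come from ``metadata['role']`` when given; otherwise every
    sample is treated as a specimen.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    counts = frame.T
    counts.index.name = "sample_id"
    if metadata is not None:
        missing = [s for s in counts.index if s not in metadata.index]
        if missing:
            raise ValueError(f"{path}: samples missing from metadata: {missing[:5]}")
        roles = metadata.loc[counts.index, "role"]
    else:
        roles = pd.Series("specimen", index=counts.index)
    return CountTable(counts, roles)


def read_taxonomy_tsv(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    return tax


def read_function_tsv(path, kind: str = "ko") -> FunctionTable:
    """PICRUSt2-style function x sample TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.T
    values.index.name = "sample_id"
    return FunctionTable(values, kind=kind)


def read_gene_sets(path) -> list[GeneSet]:
    """Gene sets from GMT (.gmt) or three-column TSV."""
    path = Path(path)
    if path.suffix == ".gmt":
        sets = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {line!r}")
            sets.append(
                GeneSet(set_id=fields[0], name=fields[1], members=frozenset(fields[2:]))
            )
        return sets
    from .functions import load_gene_sets

    return load_gene_sets(path)


def read_alias_yaml(path) -> dict:
    """Alias map YAML: instrument -> {column header -> canonical name},
    plus registered unit conversions ("from->to": factor)."""
    data = yaml.safe_load(Path(path).read_text())
    aliases = data.get("aliases", {})
    conversions = {}
    for key, factor in (data.get("unit_conversions") or {}).items():
        src, dst = key.split("->")
        conversions[(src, dst)] = float(factor)
    return {"aliases": aliases, "unit_conversions": conversions}
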