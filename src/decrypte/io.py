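"""Tabular input/output for the screen pipeline.

Sample columns use the dialect ``<drug>.<dose_nM>.<replicate>`` with
vehicle (DMSO) samples encoded as dose 0, e.g. ``D03.1000.1`` or
``D03.0.2``.  All files are plain tab-separated text.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "MaxQuantSchema",
    "IntensityTable",
    "AnnotationMap",
    "DrugTable",
    "parse_sample_key",
    "format_sample_key",
    "read_protein_groups",
    "write_table",
    "read_table",
    "write_calls_per_class",
    "write_annotation",
    "read_annotation",
    "read_keyvalue_config",
    "write_keyvalue_config",
]

log = logging.getLogger("decrypte.io")


@dataclass(frozen=True)
class SampleKey:
    drug_id: str
    dose_nM: float
    replicate: int

    @property
    def is_vehicle(self) -> bool:
        return self.dose_nM == 0.0


def parse_sample_key(key: str) -> SampleKey:
    parts = key.rsplit(".", 2)
    if len(parts) != 3:
        raise ValueError(f"sample key {key!r} is not '<drug>.<dose_nM>.<rep>'")
    drug, dose, rep = parts
    return SampleKey(drug, float(dose), int(rep))


def format_sample_key(drug_id: str, dose_nM: float, replicate: int) -> str:
    dose = int(dose_nM) if float(dose_nM).is_integer() else dose_nM
    return f"{drug_id}.{dose:g}.{replicate}"


def _sample_frame(keys: Iterable[str]) -> pd.DataFrame:
    rows = []
    for key in keys:
        sk = parse_sample_key(key)
        rows.append((key, sk.drug_id, sk.dose_nM, sk.replicate, sk.is_vehicle))
    return pd.DataFrame(rows, columns=["sample", "drug_id", "dose_nM",
                                       "replicate", "is_vehicle"]).set_index("sample")


@dataclass
class IntensityTable:
    """Protein x sample LFQ intensities with optional companion tables.

    ``intensities`` is indexed by protein id with sample-key columns;
    missing quantifications are NaN (LFQ zeros denote non-quantification
    and are converted on read).  ``peptide_counts`` shares the layout,
    ``ibaq`` holds per-vehicle-sample iBAQ abundances.
    """

    intensities: pd.DataFrame
    peptide_counts: Optional[pd.DataFrame] = None
    ibaq: Optional[pd.DataFrame] = None
    n_filtered: int = 0
    samples: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        cols = list(self.intensities.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate sample keys in intensity table")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative intensities")
        self.samples = _sample_frame(cols)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    def drug_ids(self) -> list[str]:
        ids = self.samples.loc[~self.samples.is_vehicle, "drug_id"].unique()
        return sorted(ids)

    def plate_columns(self, drug_id: str) -> tuple[list[str], list[str]]:
        """(dose columns sorted by dose, vehicle columns) of one plate."""
        sub = self.samples[self.samples.drug_id == drug_id]
        dose = sub[~sub.is_vehicle].sort_values(["dose_nM", "replicate"])
        veh = sub[sub.is_vehicle].sort_values("replicate")
        return list(dose.index), list(veh.index)

    def mean_vehicle_intensity(self) -> pd.Series:
        veh_cols = list(self.samples.index[self.samples.is_vehicle])
        return self.intensities[veh_cols].mean(axis=1)

    def mean_vehicle_ibaq(self) -> pd.Series:
        if self.ibaq is None:
            raise ValueError("no iBAQ table attached")
        return self.ibaq.mean(axis=1)


@dataclass
class AnnotationMap:
    """Flat term -> protein-set annotation over an explicit universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe is empty")
        self.terms = {t: frozenset(m) for t, m in self.terms.items()}
        stray = set().union(*self.terms.values()) - set(self.universe) \
            if self.terms else set()
        if stray:
            raise ValueError(f"annotated ids outside universe: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class DrugTable:
    """Per-drug metadata: tested doses, designated targets, drug class."""

    drugs: pd.DataFrame  # index drug_id; columns: targets (tuple), drug_class

    def targets_of(self, drug_id: str) -> tuple[str, ...]:
        return tuple(self.drugs.loc[drug_id, "targets"])


@dataclass
class MaxQuantSchema:
    """Column patterns of a MaxQuant-style proteinGroups table."""

    id_col: str = "Protein IDs"
    intensity_prefix: str = "LFQ intensity "
    peptide_prefix: str = "Unique peptides "
    ibaq_prefix: str = "iBAQ "
    flag_cols: tuple[str, ...] = ("Reverse", "Potential contaminant",
                                  "Contaminant", "Only identified by site")


def read_protein_groups(path, schema: Optional[MaxQuantSchema] = None) -> IntensityTable:
    """Read a MaxQuant-style proteinGroups TSV into an :class:`IntensityTable`.

    Rows flagged ``+`` in decoy/contaminant/identified-by-site columns are
    dropped when those columns exist; zero intensities become missing.
    """
    schema = schema or MaxQuantSchema()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if schema.id_col not in df.columns:
        raise ValueError(f"missing protein-id column {schema.id_col!r}")

    n_before = len(df)
    for col in schema.flag_cols:
        if col in df.columns:
            df = df[df[col].fillna("") != "+"]
    n_filtered = n_before - len(df)
    if n_filtered:
        log.info("removed %d flagged rows", n_filtered)

    df = df.set_index(schema.id_col)
    if df.index.duplicated().any():
        raise ValueError("duplicate protein ids")

    def block(prefix: str) -> Optional[pd.DataFrame]:
        cols = [c for c in df.columns if c.startswith(prefix)]
        if not cols:
            return None
        sub = df[cols].apply(pd.to_numeric, errors="raise")
        sub.columns = [c[len(prefix):] for c in cols]
        return sub

    inten = block(schema.intensity_prefix)
    if inten is None:
        raise ValueError("no intensity columns matched "
                         f"{schema.intensity_prefix!r}")
    inten = inten.replace(0.0, np.nan)
    peps = block(schema.peptide_prefix)
    ibaq = block(schema.ibaq_prefix)
    if ibaq is not None:
        ibaq = ibaq.replace(0.0, np.nan)
    return IntensityTable(intensities=inten, peptide_counts=peps,
                          ibaq=ibaq, n_filtered=n_filtered)


# ---------------------------------------------------------------------------
# generic result tables

def write_table(df: pd.DataFrame, path, sort_by: Optional[list[str]] = None) -> None:
    """Write a result table as TSV with deterministic row order.

    Rows are sorted by ``sort_by`` (default: all non-float columns in
    order), columns keep their given order; floats round-trip exactly.
    """
    out = df.copy()
    if sort_by is None:
        sort_by = [c for c in out.columns
                   if not pd.api.types.is_float_dtype(out[c])]
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls_per_class(calls: pd.DataFrame, out_dir,
                          label_col: str = "final_label") -> dict[str, Path]:
    """Export regulation calls into one TSV per class (up/down/not)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label in ("up", "down", "not"):
        sub = calls[calls[label_col] == label]
        p = out_dir / f"calls_{label}.txt"
        write_table(sub, p)
        paths[label] = p
    return paths


def write_annotation(annotation: AnnotationMap, path) -> None:
    rows = [(term, pid)
            for term in sorted(annotation.terms)
            for pid in sorted(annotation.terms[term])]
    pd.DataFrame(rows, columns=["term_id", "protein_id"]).to_csv(
        path, sep="\t", index=False)


def read_annotation(path, universe: Optional[Iterable[str]] = None) -> AnnotationMap:
    """Read a two-column (term_id, protein_id) TSV.

    ``universe`` defaults to the union of annotated ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms: dict[str, set[str]] = {}
    for term, pid in zip(df["term_id"], df["protein_id"]):
        terms.setdefault(term, set()).add(pid)
    if universe is None:
        universe = set().union(*terms.values()) if terms else {"_"}
    return AnnotationMap(terms={t: frozenset(m) for t, m in terms.items()},
                         universe=frozenset(universe))


# ---------------------------------------------------------------------------
# plain key=value run configuration

_KV_RE = re.compile(r"^\s*([A-Za-z_][\w.]*)\s*=\s*(.*?)\s*$")


def read_keyvalue_config(path) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        if not line.strip():
            continue
        m = _KV_RE.match(line)
        if not m:
            raise ValueError(f"unparsable config line: {line!r}")
        out[m.group(1)] = m.group(2)
    return out


def write_keyvalue_config(values: Mapping[str, object], path) -> None:
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")
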