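"""Reading, validation and filtering of assay-metadata and bioactivity tables.

The data model mirrors a ChEMBL-style assay export (one row per assay, with a
free-text ``description`` plus categorical metadata) and a Papyrus-style
bioactivity export (one row per measurement, with a pChEMBL value linking a
compound, a protein target and an assay).  Every filter appends an entry to
the container's provenance so a processed table carries its own history.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError

#: metadata fields of an assay record, in canonical order (the free-text
#: description and the identifier are handled separately)
ASSAY_METADATA_FIELDS = (
    "relationship_type",
    "standard_type",
    "src_id",
    "confidence_score",
    "bao_format",
    "curated_by",
    "assay_type",
    "tax_id",
    "pref_name",
)

ASSAY_FIELDS = ("assay_id", "description") + ASSAY_METADATA_FIELDS

BIOACTIVITY_FIELDS = (
    "compound_id",
    "smiles",
    "target_accession",
    "pchembl",
    "assay_id",
    "standard_type",
    "quality_flag",
    "censored",
    "mw",
)

_MANDATORY_ASSAY = ("assay_id", "description", "assay_type", "standard_type", "bao_format")
_MANDATORY_BIOACTIVITY = ("compound_id", "smiles", "target_accession", "pchembl", "assay_id")


@dataclass
class AssayRecord:
    """One assay: its free-text description plus categorical metadata."""

    assay_id: str
    description: str
    assay_type: str
    standard_type: str
    bao_format: str
    tax_id: str | None = None
    confidence_score: str | None = None
    relationship_type: str | None = None
    src_id: str | None = None
    curated_by: str | None = None
    pref_name: str | None = None


@dataclass
class AssayCorpus:
    """Ordered collection of assay records with a filter history."""

    records: list[AssayRecord]
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def assay_ids(self) -> list[str]:
        return [r.assay_id for r in self.records]

    @property
    def descriptions(self) -> list[str]:
        return [r.description for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [{f.name: getattr(r, f.name) for f in fields(AssayRecord)} for r in self.records]
        return pd.DataFrame(rows, columns=list(ASSAY_FIELDS))

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


@dataclass
class BioactivityPoint:
    """One (compound, target, assay) measurement on the pChEMBL scale."""

    compound_id: str
    smiles: str
    target_accession: str
    pchembl: float
    assay_id: str | None
    standard_type: str | None = None
    quality_flag: str | None = None
    censored: bool = False
    mw: float | None = None


@dataclass
class BioactivityTable:
    """Ordered collection of bioactivity points with a filter history."""

    points: list[BioactivityPoint]
    provenance: list[dict] = field(default_factory=list)
    rejects: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = [{f.name: getattr(p, f.name) for f in fields(BioactivityPoint)} for p in self.points]
        return pd.DataFrame(rows, columns=list(BIOACTIVITY_FIELDS))

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def unresolved_assay_ids(self, corpus: AssayCorpus) -> set[str]:
        known = set(corpus.assay_ids)
        return {p.assay_id for p in self.points if p.assay_id is not None and p.assay_id not in known}


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _clean(value) -> str | None:
    """Normalize a raw table cell to str, with None as the explicit missing marker."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s if s else None


def read_assay_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> AssayCorpus:
    """Read a ChEMBL-style assay export into an :class:`AssayCorpus`.

    ``column_map`` maps toolkit field names to column names in the file;
    unmapped fields default to identically named columns.  Rows with a
    missing description violate the record invariant and are collected into
    the provenance as rejects.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=True)

    for fld in _MANDATORY_ASSAY:
        col = column_map.get(fld, fld)
        if col not in frame.columns:
            raise SchemaError(f"mandatory column {col!r} (field {fld!r}) missing from {path.name}")

    records: list[AssayRecord] = []
    n_missing_description = 0
    for _, row in frame.iterrows():
        values = {}
        for fld in ASSAY_FIELDS:
            col = column_map.get(fld, fld)
            values[fld] = _clean(row[col]) if col in frame.columns else None
        if values["description"] is None:
            n_missing_description += 1
            continue
        for fld in _MANDATORY_ASSAY:
            if values[fld] is None:
                values[fld] = ""
        records.append(AssayRecord(**values))

    ids = [r.assay_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise IntegrityError(f"duplicate assay_id values: {dupes}")

    corpus = AssayCorpus(records)
    corpus.log("read_assay_table", source=str(path), n_rows=len(frame),
               n_records=len(records), n_missing_description=n_missing_description)
    return corpus


def filter_assay_corpus(
    corpus: AssayCorpus,
    max_description_chars: int = 500,
    allowed_assay_types: Iterable[str] = ("B", "F"),
) -> AssayCorpus:
    """Keep binding/functional assays with descriptions of at most 500 characters.

    Length is counted in Unicode characters after stripping surrounding
    whitespace; both rules are strict per the source conventions ("more than
    500 characters" removed, so exactly 500 is retained).
    """
    allowed = set(allowed_assay_types)
    kept: list[AssayRecord] = []
    n_long = n_type = 0
    for rec in corpus.records:
        if rec.assay_type not in allowed:
            n_type += 1
            continue
        if len(rec.description.strip()) > max_description_chars:
            n_long += 1
            continue
        kept.append(rec)
    out = AssayCorpus(kept, provenance=list(corpus.provenance))
    out.log("filter_assay_corpus", max_description_chars=max_description_chars,
            allowed_assay_types=sorted(allowed), removed_long_description=n_long,
            removed_assay_type=n_type)
    if not kept:
        warnings.warn("filter_assay_corpus produced an empty corpus")
    return out


def _parse_bool(value) -> bool:
    s = _clean(value)
    if s is None:
        return False
    return s.lower() in {"1", "true", "t", "yes", "y"}


def read_bioactivity_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> BioactivityTable:
    """Read a Papyrus-style bioactivity export.

    SMILES are stored verbatim (standardization happens at featurization
    time).  Uncensored rows whose pChEMBL value does not parse as a finite
    number are diverted to ``table.rejects`` with a reason.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=True)

    for fld in _MANDATORY_BIOACTIVITY:
        col = column_map.get(fld, fld)
        if col not in frame.columns:
            raise SchemaError(f"mandatory column {col!r} (field {fld!r}) missing from {path.name}")

    points: list[BioactivityPoint] = []
    reject_rows: list[dict] = []
    for idx, row in frame.iterrows():
        raw = {}
        for fld in BIOACTIVITY_FIELDS:
            col = column_map.get(fld, fld)
            raw[fld] = _clean(row[col]) if col in frame.columns else None
        censored = _parse_bool(raw["censored"])
        try:
            pchembl = float(raw["pchembl"]) if raw["pchembl"] is not None else float("nan")
        except (TypeError, ValueError):
            pchembl = float("nan")
        if not censored and not math.isfinite(pchembl):
            reject_rows.append({"row": idx, "reason": "unparsable pchembl",
                                "pchembl": raw["pchembl"]})
            continue
        mw = None
        if raw["mw"] is not None:
            try:
                mw = float(raw["mw"])
            except ValueError:
                mw = None
        points.append(BioactivityPoint(
            compound_id=raw["compound_id"] or "", smiles=raw["smiles"] or "",
            target_accession=raw["target_accession"] or "", pchembl=pchembl,
            assay_id=raw["assay_id"], standard_type=raw["standard_type"],
            quality_flag=raw["quality_flag"], censored=censored, mw=mw))

    table = BioactivityTable(points, rejects=pd.DataFrame(reject_rows, columns=["row", "reason", "pchembl"]))
    table.log("read_bioactivity_table", source=str(path), n_rows=len(frame),
              n_points=len(points), n_rejected=len(reject_rows))
    return table


def filter_bioactivity(
    table: BioactivityTable,
    max_mw: float = 1000.0,
    min_unique_compounds_per_target: int = 100,
    drop_low_quality: bool = True,
    drop_censored: bool = True,
    low_quality_values: Iterable[str] = ("low",),
    exclude_documents: Iterable[str] | None = None,
) -> BioactivityTable:
    """Apply standard curation filters to a bioactivity table.

    Row-level rules (order-independent): censored values, low-quality flags,
    molecular weight above ``max_mw`` Da, and an optional user-supplied
    exclusion list of assay/document identifiers (e.g. allosteric-modulator
    publications).  The target-level rule — keep only targets with strictly
    more than ``min_unique_compounds_per_target`` unique compounds — runs
    last, on the surviving rows.
    """
    low_values = {v.lower() for v in low_quality_values}
    excluded = set(exclude_documents or ())
    counts = {"censored": 0, "low_quality": 0, "mw": 0, "excluded_document": 0,
              "target_compound_count": 0}

    kept: list[BioactivityPoint] = []
    for p in table.points:
        if drop_censored and p.censored:
            counts["censored"] += 1
            continue
        if drop_low_quality and p.quality_flag is not None and p.quality_flag.lower() in low_values:
            counts["low_quality"] += 1
            continue
        if p.mw is not None and p.mw > max_mw:
            counts["mw"] += 1
            continue
        if p.assay_id is not None and p.assay_id in excluded:
            counts["excluded_document"] += 1
            continue
        kept.append(p)

    per_target: dict[str, set[str]] = {}
    for p in kept:
        per_target.setdefault(p.target_accession, set()).add(p.compound_id)
    ok_targets = {t for t, comps in per_target.items()
                  if len(comps) > min_unique_compounds_per_target}
    final = [p for p in kept if p.target_accession in ok_targets]
    counts["target_compound_count"] = len(kept) - len(final)

    out = BioactivityTable(final, provenance=list(table.provenance), rejects=table.rejects)
    out.log("filter_bioactivity", max_mw=max_mw,
            min_unique_compounds_per_target=min_unique_compounds_per_target,
            drop_low_quality=drop_low_quality, drop_censored=drop_censored,
            removed=counts)
    if not final:
        warnings.warn("filter_bioactivity produced an empty table")
    return out


def compute_pchembl(value: float) -> float:
    """pChEMBL value of a molar activity/affinity: ``-log10(value)``."""
    if not (isinstance(value, (int, float)) and math.isfinite(value)) or value <= 0:
        raise DomainError(f"pChEMBL requires a positive finite molar value, got {value!r}")
    return -math.log10(value)


def write_assay_table(corpus: AssayCorpus, path: str | Path) -> None:
    corpus.to_frame().to_csv(path, sep="\t", index=False)


def write_bioactivity_table(table: BioactivityTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame["censored"] = frame["censored"].map({True: "true", False: "false"})
    frame.to_csv(path, sep="\t", index=False)


def write_provenance(obj: AssayCorpus | BioactivityTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj.provenance, indent=2, default=str) + "\n")
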