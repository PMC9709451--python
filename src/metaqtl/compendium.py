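"""Data model and summary statistics for a multi-study QTL compendium.

A compendium is the tabular output of a literature review: one row per
reported QTL, carrying the mapping metadata (population type and size,
LOD, phenotypic variance explained) needed to re-estimate confidence
intervals, plus study-level rows describing each mapping population.

External files are TSV with fixed, documented headers (see
:data:`QTL_COLUMNS`, :data:`STUDY_COLUMNS`, :data:`MQTL_COLUMNS`); a
column-remapping dict lets callers ingest tables with other headers.
PVE is stored in percent externally, as printed in the literature, and
converted to a proportion at module boundaries where formulas need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRAITS = ("SF", "PN", "GNP", "TGW")
POPULATION_TYPES = ("RIL", "DH", "BC", "F2")
N_CHROMOSOMES = 12

QTL_COLUMNS = [
    "qtl_id", "study_id", "trait", "chr", "peak_cm", "lod", "pve_pct",
    "flank_left", "flank_right", "map_id",
]
STUDY_COLUMNS = [
    "study_id", "parents", "pop_type", "pop_size", "n_markers",
    "marker_types", "traits", "citation",
]
MQTL_COLUMNS = [
    "name", "chr", "position_cm", "flank_left", "flank_right",
    "n_qtls", "n_traits", "traits", "avg_pve_pct",
]

_NA_VALUES = ("", "NA")


@dataclass(frozen=True)
class StudyRecord:
    """One mapping study contributing QTLs to the compendium."""

    study_id: str
    parents: str
    population_type: str
    population_size: int
    n_markers: int
    marker_types: frozenset[str]
    traits: frozenset[str]
    citation: str = ""

    def __post_init__(self) -> None:
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(f"unknown population type {self.population_type!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not self.traits or not self.traits <= set(TRAITS):
            raise ValueError(f"traits must be a non-empty subset of {TRAITS}")


@dataclass(frozen=True)
class QTLRecord:
    """One literature-reported QTL.

    ``peak_cm`` is the peak position on the source study's genetic map;
    ``pve`` is the phenotypic variance explained in percent (0, 100];
    both ``lod`` and ``pve`` may be missing (None) and are imputed later.
    ``ci_reported_cm`` optionally carries the study's own 95% CI width
    for sensitivity analyses that bypass the re-estimation formula.
    """

    qtl_id: str
    study_id: str
    trait: str
    chromosome: int
    peak_cm: float | None
    lod: float | None = None
    pve: float | None = None
    flank_left: str | None = None
    flank_right: str | None = None
    source_map_id: str | None = None
    ci_reported_cm: float | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait code {self.trait!r}")
        if not 1 <= self.chromosome <= N_CHROMOSOMES:
            raise ValueError("chromosome out of range")
        if self.peak_cm is not None and self.peak_cm < 0:
            raise ValueError("peak_cm must be non-negative")
        if self.lod is not None and self.lod < 0:
            raise ValueError("lod must be non-negative")
        if self.pve is not None and not 0 < self.pve <= 100:
            raise ValueError("pve (percent) must lie in (0, 100]")


@dataclass(frozen=True)
class MQTLSummaryRow:
    """One row of a published meta-QTL summary table.

    ``n_traits`` and ``traits`` are stored as printed and are not
    cross-validated against each other (published tables occasionally
    disagree between the two columns).
    """

    name: str
    chromosome: int
    position_cm: float
    flank_left: str
    flank_right: str
    n_qtls: int
    n_traits: int
    traits: frozenset[str]
    avg_pve: float

    def __post_init__(self) -> None:
        if self.n_qtls < 1:
            raise ValueError("n_qtls must be >= 1")
        if not 1 <= self.n_traits <= len(TRAITS):
            raise ValueError("n_traits out of range")
        if not self.traits <= set(TRAITS):
            raise ValueError("unknown trait code in traits")


@dataclass
class ValidationFailure:
    row: int
    reason: str


def _read_tsv(path, columns: Sequence[str], rename: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        na_values=list(_NA_VALUES),
    )
    if rename:
        df = df.rename(columns=dict(rename))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in _NA_VALUES:
        return None
    return float(s)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s not in _NA_VALUES else None


def _split_codes(raw: str) -> frozenset[str]:
    return frozenset(t.strip() for t in str(raw).replace(";", ",").split(",") if t.strip())


def read_qtl_table(
    path, rename: Mapping[str, str] | None = None
) -> tuple[list[QTLRecord], list[ValidationFailure]]:
    """Read a QTL compendium TSV into validated records.

    Rows failing validation are collected with their (1-based, data) row
    number and the reason, never silently dropped.
    """
    df = _read_tsv(path, QTL_COLUMNS, rename)
    records: list[QTLRecord] = []
    rejects: list[ValidationFailure] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chrom = int(str(row.chr).strip())
            if not 1 <= chrom <= N_CHROMOSOMES:
                raise ValueError("chromosome out of range")
            rec = QTLRecord(
                qtl_id=str(row.qtl_id).strip(),
                study_id=str(row.study_id).strip(),
                trait=str(row.trait).strip(),
                chromosome=chrom,
                peak_cm=_opt_float(row.peak_cm),
                lod=_opt_float(row.lod),
                pve=_opt_float(row.pve_pct),
                flank_left=_opt_str(row.flank_left),
                flank_right=_opt_str(row.flank_right),
                source_map_id=_opt_str(row.map_id),
                ci_reported_cm=_opt_float(getattr(row, "ci_reported_cm", None)),
            )
            records.append(rec)
        except (ValueError, TypeError) as exc:
            rejects.append(ValidationFailure(row=i, reason=str(exc)))
    return records, rejects


def write_qtl_table(records: Iterable[QTLRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "qtl_id": r.qtl_id, "study_id": r.study_id, "trait": r.trait,
            "chr": r.chromosome, "peak_cm": r.peak_cm, "lod": r.lod,
            "pve_pct": r.pve, "flank_left": r.flank_left,
            "flank_right": r.flank_right, "map_id": r.source_map_id,
        })
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_study_table(
    path, rename: Mapping[str, str] | None = None
) -> tuple[list[StudyRecord], list[ValidationFailure]]:
    df = _read_tsv(path, STUDY_COLUMNS, rename)
    records: list[StudyRecord] = []
    rejects: list[ValidationFailure] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(StudyRecord(
                study_id=str(row.study_id).strip(),
                parents=str(row.parents).strip(),
                population_type=str(row.pop_type).strip(),
                population_size=int(str(row.pop_size).strip()),
                n_markers=int(str(row.n_markers).strip()),
                marker_types=_split_codes(row.marker_types),
                traits=_split_codes(row.traits),
                citation=str(row.citation).strip(),
            ))
        except (ValueError, TypeError) as exc:
            rejects.append(ValidationFailure(row=i, reason=str(exc)))
    return records, rejects


def read_mqtl_table(
    path, rename: Mapping[str, str] | None = None
) -> tuple[list[MQTLSummaryRow], list[ValidationFailure]]:
    df = _read_tsv(path, MQTL_COLUMNS, rename)
    rows: list[MQTLSummaryRow] = []
    rejects: list[ValidationFailure] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rows.append(MQTLSummaryRow(
                name=str(row.name).strip(),
                chromosome=int(str(row.chr).strip()),
                position_cm=float(row.position_cm),
                flank_left=str(row.flank_left).strip(),
                flank_right=str(row.flank_right).strip(),
                n_qtls=int(str(row.n_qtls).strip()),
                n_traits=int(str(row.n_traits).strip()),
                traits=_split_codes(row.traits),
                avg_pve=float(row.avg_pve_pct),
            ))
        except (ValueError, TypeError) as exc:
            rejects.append(ValidationFailure(row=i, reason=str(exc)))
    return rows, rejects


def load_study_summary_fixture() -> list[StudyRecord]:
    """Packaged transcription of the 47-study summary table."""
    with resources.as_file(resources.files("metaqtl.data") / "table1.tsv") as p:
        records, rejects = read_study_table(p)
    if rejects:  # pragma: no cover - packaged data is valid
        raise RuntimeError(f"packaged study fixture failed validation: {rejects}")
    return records


def load_mqtl_summary_fixture() -> list[MQTLSummaryRow]:
    """Packaged transcription of the published 62-MQTL summary table."""
    with resources.as_file(resources.files("metaqtl.data") / "table2.tsv") as p:
        rows, rejects = read_mqtl_table(p)
    if rejects:  # pragma: no cover
        raise RuntimeError(f"packaged MQTL fixture failed validation: {rejects}")
    return rows


def summarize_compendium(
    qtls: Sequence[QTLRecord], studies: Sequence[StudyRecord]
) -> dict:
    """Aggregate counts and ranges over a QTL compendium.

    Returns population-type counts, QTL counts per chromosome and per
    trait, min/max/mean of PVE, LOD and population size, and the
    fraction of QTLs (with a reported PVE) below 10% PVE.
    """
    if not studies:
        raise ValueError("empty study collection")
    pop_counts: dict[str, int] = {p: 0 for p in POPULATION_TYPES}
    for s in studies:
        pop_counts[s.population_type] += 1
    sizes = np.array([s.population_size for s in studies], dtype=float)

    per_chr = {c: 0 for c in range(1, N_CHROMOSOMES + 1)}
    per_trait = {t: 0 for t in TRAITS}
    for q in qtls:
        per_chr[q.chromosome] += 1
        per_trait[q.trait] += 1
    pves = np.array([q.pve for q in qtls if q.pve is not None], dtype=float)
    lods = np.array([q.lod for q in qtls if q.lod is not None], dtype=float)

    def _stats(x: np.ndarray) -> dict:
        if x.size == 0:
            return {"min": None, "max": None, "mean": None}
        return {"min": float(x.min()), "max": float(x.max()), "mean": float(x.mean())}

    return {
        "n_studies": len(studies),
        "n_qtls": len(qtls),
        "population_type_counts": pop_counts,
        "population_size": _stats(sizes),
        "qtls_per_chromosome": per_chr,
        "qtls_per_trait": per_trait,
        "pve_pct": _stats(pves),
        "lod": _stats(lods),
        "fraction_pve_lt_10": float((pves < 10.0).mean()) if pves.size else None,
    }


def summarize_mqtl_table(rows: Sequence[MQTLSummaryRow]) -> dict:
    """Aggregate a meta-QTL summary table.

    ``counts_at_least[t]`` counts rows with at least ``t`` member QTLs
    for every threshold t up to the observed maximum.
    """
    if not rows:
        raise ValueError("empty MQTL table")
    n_qtls = np.array([r.n_qtls for r in rows])
    pve = np.array([r.avg_pve for r in rows], dtype=float)
    per_chr: dict[int, int] = {}
    for r in rows:
        per_chr[r.chromosome] = per_chr.get(r.chromosome, 0) + 1
    max_members = int(n_qtls.max())
    return {
        "n_mqtls": len(rows),
        "total_member_qtls": int(n_qtls.sum()),
        "mqtls_per_chromosome": dict(sorted(per_chr.items())),
        "avg_pve": {"min": float(pve.min()), "max": float(pve.max()),
                    "mean": float(pve.mean())},
        "counts_at_least": {t: int((n_qtls >= t).sum())
                            for t in range(1, max_members + 1)},
        "n_singletons": int((n_qtls == 1).sum()),
    }
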