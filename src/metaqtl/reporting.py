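"""Stability filtering, CI fold-reduction statistics, and GWAS co-location.

An MQTL supported by many independent QTLs is more likely to mark a
real, background-independent locus; the stability filter keeps MQTLs
with at least ``threshold`` member QTLs (default 6).  Fold reduction
quantifies how much consensus clustering narrows confidence intervals:
mean initial CI / mean MQTL CI, reported overall and per chromosome
(the per-chromosome maximum is what "up to X-fold" headlines refer to).
Co-location checks whether an MQTL's physical interval lies within a
window of a GWAS peak SNP on the same chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta import MQTL


@dataclass(frozen=True)
class GWASLocus:
    locus_id: str
    chromosome: int
    position_bp: int
    trait: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError("position_bp must be >= 1")


GWAS_COLUMNS = ["locus_id", "chr", "pos_bp", "trait", "source"]


def read_gwas_table(path) -> list[GWASLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "trait": str, "source": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        GWASLocus(str(r.locus_id), int(r.chr), int(r.pos_bp), str(r.trait),
                  str(r.source))
        for r in df.itertuples()
    ]


@dataclass
class StabilityReport:
    stable_names: list[str]
    threshold: int
    per_chromosome: dict[int, int]
    stable: list[MQTL] = field(default_factory=list, repr=False)


def stable_filter(mqtls: Sequence[MQTL], threshold: int = 6) -> StabilityReport:
    """Keep MQTLs with at least ``threshold`` member QTLs, in map order."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    stable = sorted(
        (m for m in mqtls if m.n_qtls >= threshold),
        key=lambda m: (m.chromosome, m.position_cm),
    )
    per_chrom: dict[int, int] = {}
    for m in stable:
        per_chrom[m.chromosome] = per_chrom.get(m.chromosome, 0) + 1
    return StabilityReport(
        stable_names=[m.name for m in stable],
        threshold=threshold,
        per_chromosome=per_chrom,
        stable=stable,
    )


def ci_fold_reduction(
    initial_cis: Sequence[float], mqtl_cis: Sequence[float]
) -> float:
    """Mean initial CI width divided by mean MQTL CI width."""
    if not len(initial_cis) or not len(mqtl_cis):
        raise ValueError("both CI lists must be non-empty")
    mean_mqtl = float(np.mean(mqtl_cis))
    if mean_mqtl == 0:
        raise ValueError("zero mean MQTL CI")
    return float(np.mean(initial_cis)) / mean_mqtl


def fold_reduction_summary(
    initial_by_chrom: Mapping[int, Sequence[float]],
    mqtl_by_chrom: Mapping[int, Sequence[float]],
) -> dict:
    """Overall, per-chromosome, and maximum per-chromosome fold reduction."""
    per_chrom = {
        c: ci_fold_reduction(initial_by_chrom[c], mqtl_by_chrom[c])
        for c in sorted(set(initial_by_chrom) & set(mqtl_by_chrom))
        if len(initial_by_chrom[c]) and len(mqtl_by_chrom[c])
    }
    all_initial = [w for v in initial_by_chrom.values() for w in v]
    all_mqtl = [w for v in mqtl_by_chrom.values() for w in v]
    return {
        "overall": ci_fold_reduction(all_initial, all_mqtl),
        "per_chromosome": per_chrom,
        "max_per_chromosome": max(per_chrom.values()) if per_chrom else None,
    }


def gwas_colocate(
    intervals: Sequence[tuple[str, int, int, int, frozenset[str] | set[str]]],
    loci: Sequence[GWASLocus],
    window_bp: int = 0,
) -> pd.DataFrame:
    """Co-locate MQTL physical intervals with GWAS peak loci.

    ``intervals`` holds (mqtl_name, chromosome, start_bp, end_bp,
    traits).  A locus co-locates with an interval when its distance to
    the interval is at most ``window_bp`` and the chromosomes match.
    Both trait-agnostic and trait-matched hits are reported.
    """
    rows = []
    for name, chrom, start, end, traits in intervals:
        for locus in loci:
            if locus.chromosome != chrom:
                continue
            dist = max(start - locus.position_bp, locus.position_bp - end, 0)
            if dist <= window_bp:
                rows.append({
                    "mqtl_name": name, "chr": chrom, "locus_id": locus.locus_id,
                    "pos_bp": locus.position_bp, "distance_bp": int(dist),
                    "locus_trait": locus.trait,
                    "trait_match": locus.trait in traits,
                })
    return pd.DataFrame(
        rows, columns=["mqtl_name", "chr", "locus_id", "pos_bp", "distance_bp",
                       "locus_trait", "trait_match"],
    )


REQUIRED_SECTIONS = {
    "compendium_summary": "compendium stage output absent",
    "projection_report": "projection stage output absent",
    "fits": "cluster stage output absent",
    "mqtl_table": "cluster stage output absent",
    "stability_report": "stability stage output absent",
    "colocation": "co-location stage output absent",
}


def full_report(
    *,
    compendium_summary: dict | None,
    projection_report: dict | None,
    fits: dict | None,
    mqtl_table: list | None,
    stability_report: dict | None,
    colocation: list | None,
    seed: int,
    config: dict | None = None,
) -> dict:
    """Assemble the six-section pipeline report bundle.

    Deterministic: with identical inputs and seed, serialising the
    bundle with sorted keys yields byte-identical JSON (no timestamps).
    """
    sections = {
        "compendium_summary": compendium_summary,
        "projection_report": projection_report,
        "fits": fits,
        "mqtl_table": mqtl_table,
        "stability_report": stability_report,
        "colocation": colocation,
    }
    for key, message in REQUIRED_SECTIONS.items():
        if sections[key] is None:
            raise ValueError(message)
    bundle = dict(sections)
    bundle["seed"] = seed
    bundle["config"] = config or {}
    return bundle


def write_report_json(bundle: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle, fh, sort_keys=True, indent=1)
        fh.write("\n")


MQTL_TABLE_COLUMNS = [
    "name", "chr", "position_cm", "flank_left", "flank_right",
    "n_qtls", "n_traits", "traits", "avg_pve_pct", "ci95_cm",
]


def mqtls_to_frame(mqtls: Sequence[MQTL]) -> pd.DataFrame:
    rows = [
        {
            "name": m.name, "chr": m.chromosome, "position_cm": m.position_cm,
            "flank_left": m.flank_left, "flank_right": m.flank_right,
            "n_qtls": m.n_qtls, "n_traits": len(m.traits),
            "traits": ",".join(sorted(m.traits)), "avg_pve_pct": m.avg_pve,
            "ci95_cm": m.ci95_cm,
        }
        for m in mqtls
    ]
    return pd.DataFrame(rows, columns=MQTL_TABLE_COLUMNS)
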