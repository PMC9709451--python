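"""Candidate-gene mining under stable MQTL intervals.

Stable MQTLs are resolved to physical (bp) intervals via a marker
physical-position lookup, genes overlapping those intervals are
extracted from a GFF3 annotation, GO-term enrichment of the extracted
gene set is tested with a one-sided hypergeometric test under
Benjamini-Hochberg FDR control, and genes are ranked by their
expression fold change in yield-related tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .meta import MQTL

REASON_NO_MARKER_POSITION = "NO_MARKER_POSITION"
REASON_MARKER_CHR_CONFLICT = "MARKER_CHR_CONFLICT"

#: Yield-related tissues used by default for expression ranking.
DEFAULT_TARGET_TISSUES = frozenset({
    "anther", "pistil", "seed_5dap", "seed_10dap", "embryo", "endosperm",
    "inflorescence_pre", "inflorescence_post",
})

EXPRESSION_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class PhysicalInterval:
    """1-based inclusive genomic interval of one MQTL."""

    mqtl_name: str
    chromosome: int
    start_bp: int
    end_bp: int
    source_markers: tuple[str, str]

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based; start_bp must be >= 1")

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """(chrom, start, end, name) with 0-based half-open coordinates."""
        return (f"Chr{self.chromosome}", self.start_bp - 1, self.end_bp, self.mqtl_name)


@dataclass(frozen=True)
class Unresolved:
    mqtl_name: str
    reason: str


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k_in_set: int
    K_in_background: int
    n_set: int
    N_background: int
    p_value: float
    fdr: float
    significant: bool


MARKER_POSITION_COLUMNS = ["marker", "chr", "pos_bp"]


def read_marker_positions(path) -> dict[str, tuple[int, int]]:
    """Marker -> (chromosome, bp) lookup from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str})
    missing = [c for c in MARKER_POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return {str(r.marker): (int(r.chr), int(r.pos_bp)) for r in df.itertuples()}


def resolve_physical(
    mqtl: MQTL, marker_positions: Mapping[str, tuple[int, int]]
) -> PhysicalInterval | Unresolved:
    """Resolve an MQTL's flanking markers to a physical interval.

    The interval spans [min, max] of the two markers' positions; an
    absent marker or a cross-chromosome pair yields an Unresolved with
    the corresponding reason.
    """
    flanks = (mqtl.flank_left, mqtl.flank_right)
    if any(f is None or f not in marker_positions for f in flanks):
        return Unresolved(mqtl.name, REASON_NO_MARKER_POSITION)
    (chr_l, pos_l), (chr_r, pos_r) = (marker_positions[f] for f in flanks)
    if chr_l != chr_r or chr_l != mqtl.chromosome:
        return Unresolved(mqtl.name, REASON_MARKER_CHR_CONFLICT)
    return PhysicalInterval(
        mqtl_name=mqtl.name,
        chromosome=mqtl.chromosome,
        start_bp=min(pos_l, pos_r),
        end_bp=max(pos_l, pos_r),
        source_markers=flanks,
    )


def _chrom_to_int(seqid: str) -> int | None:
    s = seqid.lower().removeprefix("chr").lstrip("0") or "0"
    return int(s) if s.isdigit() else None


def load_annotation(gff3_path) -> gffutils.FeatureDB:
    """Parse a GFF3 file into an in-memory feature database."""
    try:
        return gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc


def extract_genes(
    interval: PhysicalInterval, annotation: gffutils.FeatureDB
) -> list[GeneRecord]:
    """Genes overlapping the interval by >= 1 bp, both strands, by start."""
    genes: list[GeneRecord] = []
    for feat in annotation.features_of_type("gene"):
        chrom = _chrom_to_int(feat.seqid)
        if chrom != interval.chromosome:
            continue
        if feat.end < interval.start_bp or feat.start > interval.end_bp:
            continue
        desc = feat.attributes.get("description", [""])[0] if feat.attributes else ""
        gene_id = feat.id or feat.attributes.get("ID", ["?"])[0]
        genes.append(GeneRecord(
            gene_id=gene_id, chromosome=chrom, start_bp=feat.start,
            end_bp=feat.end, strand=feat.strand, description=desc,
        ))
    return sorted(genes, key=lambda g: (g.start_bp, g.gene_id))


GO_COLUMNS = ["gene_id", "term_id"]


def read_go_annotation(path) -> dict[str, set[str]]:
    """gene -> set of GO terms, from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.gene_id), set()).add(str(r.term_id))
    return out


def go_enrichment(
    gene_set: Sequence[str],
    annotation: Mapping[str, set[str]],
    background: Sequence[str],
    fdr_alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation with BH-FDR control.

    For each term with successes K among the N background genes, the
    upper-tail probability P(X >= k) of seeing k annotated genes in a
    draw of n = |gene_set| is computed; p-values are corrected across
    terms by Benjamini-Hochberg.
    """
    bg = list(dict.fromkeys(background))
    bg_index = set(bg)
    offenders = [g for g in gene_set if g not in bg_index]
    if offenders:
        raise ValueError(f"genes absent from background: {sorted(offenders)}")
    genes = list(dict.fromkeys(gene_set))
    N = len(bg)
    n = len(genes)
    terms: dict[str, tuple[int, int]] = {}
    gene_set_set = set(genes)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for g in bg:
        for t in annotation.get(g, ()):
            term_K[t] = term_K.get(t, 0) + 1
            if g in gene_set_set:
                term_k[t] = term_k.get(t, 0) + 1
    term_ids = sorted(term_K)
    pvals = np.array([
        hypergeom.sf(term_k.get(t, 0) - 1, N, term_K[t], n) for t in term_ids
    ])
    if len(pvals) == 0:
        return []
    reject, fdr, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    return [
        EnrichmentResult(
            term_id=t, k_in_set=term_k.get(t, 0), K_in_background=term_K[t],
            n_set=n, N_background=N, p_value=float(p), fdr=float(q),
            significant=bool(sig),
        )
        for t, p, q, sig in zip(term_ids, pvals, fdr, reject)
    ]


def expression_rank(
    genes: Sequence[str],
    expression: pd.DataFrame,
    target_tissues: frozenset[str] | set[str] = DEFAULT_TARGET_TISSUES,
    fold_threshold: float = 2.0,
    pseudocount: float = EXPRESSION_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank genes by target-tissue / other-tissue expression fold change.

    ``expression`` is genes x tissues.  The score for a gene is
    (mean over target tissues + c) / (mean over other tissues + c) with
    pseudocount c; genes at or above ``fold_threshold`` make the
    shortlist, sorted by descending score.  Genes absent from the matrix
    are excluded and returned separately.
    """
    target_cols = [c for c in expression.columns if c in target_tissues]
    if not target_cols:
        raise ValueError("no target tissue columns found in expression matrix")
    other_cols = [c for c in expression.columns if c not in target_tissues]
    missing = [g for g in genes if g not in expression.index]
    present = [g for g in genes if g in expression.index]
    rows = []
    for g in present:
        tgt = float(expression.loc[g, target_cols].mean())
        oth = float(expression.loc[g, other_cols].mean()) if other_cols else 0.0
        score = (tgt + pseudocount) / (oth + pseudocount)
        rows.append({"gene_id": g, "score": score,
                     "target_mean": tgt, "other_mean": oth})
    frame = pd.DataFrame(rows, columns=["gene_id", "score", "target_mean", "other_mean"])
    shortlist = (
        frame[frame["score"] >= fold_threshold]
        .sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return shortlist, missing


def write_bed(intervals: Sequence[PhysicalInterval], path) -> None:
    """Write MQTL physical intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, name = iv.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
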