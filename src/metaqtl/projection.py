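"""Projection of QTL peaks and confidence intervals onto the consensus map.

Each QTL position on a source study map is transferred by homothetic
(flanking-anchor) projection: the nearest shared markers flanking the
position define a linear map from source to consensus coordinates.  The
peak and the two CI endpoints (peak +/- CI/2 on the source map, clipped
to the chromosome) are projected independently, each with its own
flanking anchors, so a CI spanning several anchor intervals is handled
and the single-interval case reduces to a pure width rescaling.

Failures are never fatal: every QTL that cannot be projected is
returned as a rejection with an explicit reason code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .ci import CIEstimate, Z_95_WIDTH
from .compendium import QTLRecord
from .consensus import ConsensusMap, GeneticMap

REASON_NO_ANCHOR_LEFT = "NO_SHARED_ANCHOR_LEFT"
REASON_NO_ANCHOR_RIGHT = "NO_SHARED_ANCHOR_RIGHT"
REASON_ANCHOR_ORDER_CONFLICT = "ANCHOR_ORDER_CONFLICT"
REASON_ZERO_INTERVAL = "ZERO_INTERVAL"
REASON_MISSING_PEAK = "MISSING_PEAK"
REASON_NO_SOURCE_MAP = "NO_SOURCE_MAP"

FLAG_PEAK_FROM_FLANKS = "PEAK_FROM_FLANKS"


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL transferred to consensus coordinates with its 95% CI and sigma."""

    qtl_id: str
    chromosome: int
    peak_cons_cm: float
    ci95_cons_cm: float
    sigma_cm: float
    trait: str
    pve: float  # proportion in (0, 1]
    member_of: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ci95_cons_cm <= 0:
            raise ValueError("ci95_cons_cm must be positive")
        if abs(self.sigma_cm - self.ci95_cons_cm / Z_95_WIDTH) > 1e-9 * self.sigma_cm:
            raise ValueError("sigma_cm inconsistent with ci95_cons_cm / 3.92")


@dataclass(frozen=True)
class Rejection:
    qtl_id: str
    reason: str


@dataclass
class ProjectionReport:
    n_input: int
    n_projected: int
    n_rejected: int
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def reason_histogram(self) -> dict[str, int]:
        return dict(Counter(r.reason for r in self.rejections))


class ProjectionError(ValueError):
    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


def _flanking_anchors(
    pos: float, shared: list[tuple[str, float, float]]
) -> tuple[tuple[str, float, float], tuple[str, float, float]]:
    """Nearest shared anchors flanking ``pos`` in source coordinates.

    ``shared`` holds (marker, src_pos, cons_pos).  Raises ProjectionError
    with a NO_SHARED_ANCHOR_* reason when no anchor bounds the position.
    """
    left = None
    right = None
    for item in shared:
        src = item[1]
        if src <= pos and (left is None or src > left[1]):
            left = item
        if src >= pos and (right is None or src < right[1]):
            right = item
    if left is None:
        raise ProjectionError(REASON_NO_ANCHOR_LEFT)
    if right is None:
        raise ProjectionError(REASON_NO_ANCHOR_RIGHT)
    return left, right


def project_position(
    pos_src: float,
    left: tuple[float, float],
    right: tuple[float, float],
) -> float:
    """Linearly map ``pos_src`` through the anchor pair.

    ``left``/``right`` are (source position, consensus position) pairs
    with ``left`` source <= ``pos_src`` <= ``right`` source.
    """
    srcL, consL = left
    srcR, consR = right
    if srcL == srcR:
        if consL != consR:
            raise ProjectionError(REASON_ZERO_INTERVAL, "zero-length source anchor interval")
        return consL
    if not srcL <= pos_src <= srcR:
        raise ValueError("position outside the anchor interval")
    if srcR - srcL < 0:
        raise ProjectionError(REASON_ZERO_INTERVAL, "negative source interval")
    if consR < consL:
        raise ProjectionError(REASON_ANCHOR_ORDER_CONFLICT, "anchors inverted on consensus")
    return consL + (pos_src - srcL) * (consR - consL) / (srcR - srcL)


def _project_one(
    pos: float, shared: list[tuple[str, float, float]]
) -> float:
    left, right = _flanking_anchors(pos, shared)
    return project_position(pos, (left[1], left[2]), (right[1], right[2]))


def project_qtl(
    qtl: QTLRecord,
    ci: CIEstimate,
    source_map: GeneticMap,
    consensus: ConsensusMap,
) -> ProjectedQTL | Rejection:
    """Project one QTL's peak and CI endpoints onto the consensus map.

    The source CI is centred on the peak and clipped to the source
    chromosome bounds (asymmetrically if needed) before each endpoint is
    projected with its own flanking anchors.  When the peak position is
    missing but both reported flanking markers exist on the source map,
    their midpoint is used and the result is flagged PEAK_FROM_FLANKS.
    """
    chrom = qtl.chromosome
    flags: set[str] = set()
    src_pos = source_map.positions(chrom)
    cons_pos = consensus.positions(chrom)
    shared = [(m, p, cons_pos[m]) for m, p in src_pos.items() if m in cons_pos]

    peak = qtl.peak_cm
    if peak is None:
        if (
            qtl.flank_left in src_pos
            and qtl.flank_right in src_pos
        ):
            peak = 0.5 * (src_pos[qtl.flank_left] + src_pos[qtl.flank_right])
            flags.add(FLAG_PEAK_FROM_FLANKS)
        else:
            return Rejection(qtl.qtl_id, REASON_MISSING_PEAK)

    if not src_pos:
        return Rejection(qtl.qtl_id, REASON_NO_SOURCE_MAP)

    chrom_end = max(src_pos.values())
    half = ci.ci95_cm / 2.0
    lo = max(0.0, peak - half)
    hi = min(chrom_end, peak + half)

    try:
        peak_cons = _project_one(peak, shared)
        lo_cons = _project_one(lo, shared)
        hi_cons = _project_one(hi, shared)
    except ProjectionError as exc:
        return Rejection(qtl.qtl_id, exc.reason)

    width = hi_cons - lo_cons
    if width <= 0:
        return Rejection(qtl.qtl_id, REASON_ZERO_INTERVAL)
    return ProjectedQTL(
        qtl_id=qtl.qtl_id,
        chromosome=chrom,
        peak_cons_cm=peak_cons,
        ci95_cons_cm=width,
        sigma_cm=width / Z_95_WIDTH,
        trait=qtl.trait,
        pve=(qtl.pve or 0.0) / 100.0,
        flags=frozenset(flags),
    )


def project_all(
    qtls_with_ci: list[tuple[QTLRecord, CIEstimate]],
    source_maps: dict[str, GeneticMap],
    consensus: ConsensusMap,
) -> tuple[list[ProjectedQTL], ProjectionReport]:
    """Project a compendium; returns projected QTLs and a conserved report."""
    results: list[ProjectedQTL | Rejection] = []
    for qtl, ci in qtls_with_ci:
        smap = source_maps.get(qtl.source_map_id or "")
        if smap is None:
            results.append(Rejection(qtl.qtl_id, REASON_NO_SOURCE_MAP))
            continue
        results.append(project_qtl(qtl, ci, smap, consensus))
    return (
        [r for r in results if isinstance(r, ProjectedQTL)],
        projection_report(results),
    )


def projection_report(results: list[ProjectedQTL | Rejection]) -> ProjectionReport:
    """Count projections and rejections; n_projected + n_rejected = n_input."""
    if not results:
        raise ValueError("no projection results")
    rejections = [r for r in results if isinstance(r, Rejection)]
    return ProjectionReport(
        n_input=len(results),
        n_projected=len(results) - len(rejections),
        n_rejected=len(rejections),
        rejections=rejections,
    )


PROJECTED_COLUMNS = [
    "qtl_id", "chr", "peak_cons_cm", "ci95_cons_cm", "sigma_cm", "trait", "pve_pct",
]


def write_projected_table(projected: list[ProjectedQTL], path) -> None:
    rows = [
        {
            "qtl_id": p.qtl_id, "chr": p.chromosome,
            "peak_cons_cm": p.peak_cons_cm, "ci95_cons_cm": p.ci95_cons_cm,
            "sigma_cm": p.sigma_cm, "trait": p.trait, "pve_pct": p.pve * 100.0,
        }
        for p in projected
    ]
    pd.DataFrame(rows, columns=PROJECTED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_projected_table(path) -> list[ProjectedQTL]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProjectedQTL(
            qtl_id=str(r.qtl_id), chromosome=int(r.chr),
            peak_cons_cm=float(r.peak_cons_cm), ci95_cons_cm=float(r.ci95_cons_cm),
            sigma_cm=float(r.ci95_cons_cm) / Z_95_WIDTH, trait=str(r.trait),
            pve=float(r.pve_pct) / 100.0,
        )
        for r in df.itertuples()
    ]
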