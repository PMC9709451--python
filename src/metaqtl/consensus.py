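"""Consensus genetic-map construction by anchor-marker interpolation.

A high-density scaffold map provides the coordinate frame; markers from
component study maps are transferred onto it by linear interpolation of
their component positions between shared anchor markers.  Scaffold
positions are never altered.  Component markers whose anchors disagree
in order between the two maps, or that fall beyond the scaffold
chromosome ends under extrapolation, are dropped and reported rather
than silently placed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MapEntry:
    marker: str
    chromosome: int
    pos_cm: float


@dataclass
class GeneticMap:
    """Ordered markers with cM positions, grouped by chromosome."""

    map_id: str
    entries: list[MapEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        last: dict[int, float] = {}
        for e in self.entries:
            if e.marker in seen:
                raise ValueError(f"duplicate marker {e.marker!r} in map {self.map_id!r}")
            seen.add(e.marker)
            if e.pos_cm < 0:
                raise ValueError(f"negative position for marker {e.marker!r}")
            if e.chromosome in last and e.pos_cm < last[e.chromosome]:
                raise ValueError(
                    f"positions not non-decreasing on chromosome {e.chromosome} "
                    f"of map {self.map_id!r} (marker {e.marker!r})"
                )
            last[e.chromosome] = e.pos_cm

    def chromosomes(self) -> list[int]:
        return sorted({e.chromosome for e in self.entries})

    def chromosome_entries(self, chromosome: int) -> list[MapEntry]:
        return sorted(
            (e for e in self.entries if e.chromosome == chromosome),
            key=lambda e: e.pos_cm,
        )

    def positions(self, chromosome: int) -> dict[str, float]:
        return {e.marker: e.pos_cm for e in self.entries if e.chromosome == chromosome}

    def chromosome_length(self, chromosome: int) -> float:
        return max(e.pos_cm for e in self.entries if e.chromosome == chromosome)


@dataclass
class ConsensusMap(GeneticMap):
    """A GeneticMap with per-marker provenance and per-chromosome lengths.

    Provenance is ``"scaffold"`` for markers inherited from the scaffold
    and ``"interpolated:<map_id>"`` for markers transferred from a
    component map.
    """

    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def length_cm(self) -> dict[int, float]:
        return {c: self.chromosome_length(c) for c in self.chromosomes()}

    @property
    def cumulative_length_cm(self) -> float:
        return float(sum(self.length_cm.values()))


@dataclass
class IntegrationReport:
    """Per-chromosome accounting of component-marker integration."""

    n_added: dict[int, int] = field(default_factory=dict)
    n_dropped: dict[int, int] = field(default_factory=dict)
    drops: list[tuple[str, int, str, str]] = field(default_factory=list)
    #: (marker, chromosome, source map, reason)
    skipped_chromosomes: list[tuple[str, int, str]] = field(default_factory=list)
    #: (map_id, chromosome, reason)

    def record_drop(self, marker: str, chromosome: int, map_id: str, reason: str) -> None:
        self.drops.append((marker, chromosome, map_id, reason))
        self.n_dropped[chromosome] = self.n_dropped.get(chromosome, 0) + 1

    def record_add(self, chromosome: int) -> None:
        self.n_added[chromosome] = self.n_added.get(chromosome, 0) + 1


REASON_ORDER_CONFLICT = "anchor order conflict"
REASON_OUT_OF_RANGE = "extrapolation out of range"
REASON_DUPLICATE = "duplicate marker"
REASON_FEW_ANCHORS = "fewer than 2 shared anchors"
REASON_ZERO_SPAN = "zero component anchor span"


def build_consensus(
    scaffold: GeneticMap, components: Iterable[GeneticMap]
) -> tuple[ConsensusMap, IntegrationReport]:
    """Integrate component-map markers into the scaffold frame.

    Scaffold markers keep their positions exactly.  Each component-only
    marker lying between two shared anchors is placed by linear
    interpolation of its component position between the anchors'
    scaffold positions; markers outside the terminal anchors are
    extrapolated with the chromosome-level mean scaling ratio and
    dropped if they land beyond the scaffold chromosome ends.  Position
    ties are broken by the smallest representable float offset, in
    insertion order then alphabetically, so the result is strictly
    ordered and deterministic.
    """
    report = IntegrationReport()
    # accumulated additions: chromosome -> list of (pos, insertion_idx, marker, prov)
    added: dict[int, list[tuple[float, int, str, str]]] = {}
    placed: set[str] = {e.marker for e in scaffold.entries}
    counter = 0

    for comp in components:
        for chrom in comp.chromosomes():
            scaf_pos = scaffold.positions(chrom)
            comp_entries = comp.chromosome_entries(chrom)
            comp_pos = {e.marker: e.pos_cm for e in comp_entries}
            shared = [m for m in comp_pos if m in scaf_pos]
            if len(shared) < 2:
                report.skipped_chromosomes.append((comp.map_id, chrom, REASON_FEW_ANCHORS))
                continue
            shared.sort(key=lambda m: scaf_pos[m])
            chrom_end = scaffold.chromosome_length(chrom)
            src_first, src_last = comp_pos[shared[0]], comp_pos[shared[-1]]
            scaf_first, scaf_last = scaf_pos[shared[0]], scaf_pos[shared[-1]]
            span_ok = src_last > src_first
            ratio = (scaf_last - scaf_first) / (src_last - src_first) if span_ok else math.nan

            def place(marker: str, pos: float, prov: str) -> None:
                nonlocal counter
                added.setdefault(chrom, []).append((pos, counter, marker, prov))
                placed.add(marker)
                report.record_add(chrom)
                counter += 1

            prov = f"interpolated:{comp.map_id}"
            for e in comp_entries:
                m = e.marker
                if m in scaf_pos:
                    continue  # anchor: scaffold identity wins
                if m in placed:
                    report.record_drop(m, chrom, comp.map_id, REASON_DUPLICATE)
                    continue
                src = e.pos_cm
                if src < src_first or src > src_last:
                    # beyond terminal anchors: mean-ratio extrapolation
                    if not span_ok:
                        reason = (REASON_ORDER_CONFLICT if src_last < src_first
                                  else REASON_ZERO_SPAN)
                        report.record_drop(m, chrom, comp.map_id, reason)
                        continue
                    if src < src_first:
                        pos = scaf_first - (src_first - src) * ratio
                    else:
                        pos = scaf_last + (src - src_last) * ratio
                    if pos < 0.0 or pos > chrom_end:
                        report.record_drop(m, chrom, comp.map_id, REASON_OUT_OF_RANGE)
                        continue
                    place(m, pos, prov)
                    continue
                # find the flanking anchor interval containing src
                left = max((a for a in shared if comp_pos[a] <= src),
                           key=lambda a: comp_pos[a], default=None)
                right = min((a for a in shared if comp_pos[a] >= src),
                            key=lambda a: comp_pos[a], default=None)
                if left is None or right is None:
                    # anchors not monotone in component coordinates
                    report.record_drop(m, chrom, comp.map_id, REASON_ORDER_CONFLICT)
                    continue
                sL, sR = comp_pos[left], comp_pos[right]
                cL, cR = scaf_pos[left], scaf_pos[right]
                if sL == sR:
                    if cL == cR:
                        place(m, cL, prov)
                    else:
                        report.record_drop(m, chrom, comp.map_id, REASON_ORDER_CONFLICT)
                    continue
                if cR < cL:
                    report.record_drop(m, chrom, comp.map_id, REASON_ORDER_CONFLICT)
                    continue
                pos = cL + (src - sL) * (cR - cL) / (sR - sL)
                place(m, pos, prov)

    entries: list[MapEntry] = []
    provenance: dict[str, str] = {}
    for chrom in sorted(set(scaffold.chromosomes()) | set(added)):
        rows: list[tuple[float, int, int, str, str]] = []
        # sort key: position, tier (scaffold first), insertion order, name
        for e in scaffold.chromosome_entries(chrom):
            rows.append((e.pos_cm, 0, 0, e.marker, "scaffold"))
        for pos, idx, marker, prov in added.get(chrom, []):
            rows.append((pos, 1, idx, marker, prov))
        rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        prev = -math.inf
        for pos, _tier, _idx, marker, prov in rows:
            if pos <= prev:
                pos = np.nextafter(prev, math.inf)
            entries.append(MapEntry(marker, chrom, pos))
            provenance[marker] = prov
            prev = pos
    return ConsensusMap(map_id="consensus", entries=entries, provenance=provenance), report


def map_statistics(genetic_map: GeneticMap) -> dict:
    """Per-chromosome marker counts, lengths, and mean inter-marker density.

    Density is chromosome length / (marker count - 1); a single-marker
    chromosome has undefined density, reported as None.  The genome mean
    density averages the defined per-chromosome densities.
    """
    if not genetic_map.entries:
        raise ValueError("empty map")
    per_chrom: dict[int, dict] = {}
    for chrom in genetic_map.chromosomes():
        entries = genetic_map.chromosome_entries(chrom)
        length = entries[-1].pos_cm
        n = len(entries)
        per_chrom[chrom] = {
            "n_markers": n,
            "length_cm": length,
            "density_cm": (length / (n - 1)) if n > 1 else None,
        }
    densities = [v["density_cm"] for v in per_chrom.values() if v["density_cm"] is not None]
    return {
        "per_chromosome": per_chrom,
        "n_markers": sum(v["n_markers"] for v in per_chrom.values()),
        "cumulative_length_cm": float(sum(v["length_cm"] for v in per_chrom.values())),
        "mean_density_cm": float(np.mean(densities)) if densities else None,
    }


MAP_COLUMNS = ["map_id", "marker", "chr", "pos_cm"]


def read_map_tables(path) -> dict[str, GeneticMap]:
    """Read one or more genetic maps from a TSV (map_id, marker, chr, pos_cm)."""
    df = pd.read_csv(path, sep="\t", dtype={"map_id": str, "marker": str})
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    maps: dict[str, GeneticMap] = {}
    for map_id, group in df.groupby("map_id", sort=False):
        entries = [
            MapEntry(str(r.marker), int(r.chr), float(r.pos_cm))
            for r in group.sort_values(["chr", "pos_cm"], kind="stable").itertuples()
        ]
        maps[str(map_id)] = GeneticMap(map_id=str(map_id), entries=entries)
    return maps


def write_map_table(maps: Iterable[GeneticMap], path) -> None:
    rows = [
        {"map_id": m.map_id, "marker": e.marker, "chr": e.chromosome, "pos_cm": e.pos_cm}
        for m in maps
        for e in m.entries
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)
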