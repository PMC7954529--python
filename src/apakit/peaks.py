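"""PAS discovery: peak calling, region extension, reciprocal ortholog mapping.

Peaks are called per species from filtered read 3'-end positions: covered
positions on one (contig, strand) are clustered, clusters whose neighboring
covered bases lie within ``merge_distance`` are merged, weakly supported
clusters are dropped, and the PAS apex is the most 3' covered base of the
cluster (strand-aware).  Each apex is extended ±100 bp into a comparison
region, projected through the block map both ways (the liftover stand-in),
and the two species' reciprocal regions are merged into one catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genomes import BlockMap, GenomePair

FLANK = 100

STATUS_RECIPROCAL = "reciprocal"
STATUS_UNMAPPED_FWD = "unmapped_forward"
STATUS_UNMAPPED_REV = "unmapped_reverse"


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def call_peaks(reads: pd.DataFrame, min_reads: int = 5,
               merge_distance: int = 30) -> pd.DataFrame:
    """Cluster read 3'-ends into peaks.

    Parameters
    ----------
    reads
        Frame with contig / pos / strand columns (all samples of one species
        pooled; support is summed over samples).
    min_reads
        Minimum summed read support to keep a cluster.
    merge_distance
        Neighboring covered positions at most this far apart stay in one
        cluster.

    Returns a frame with contig, strand, start, end (half-open span of covered
    bases), apex and support, sorted by coordinate.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    rows: List[dict] = []
    if len(reads) == 0:
        return pd.DataFrame(columns=["contig", "strand", "start", "end", "apex", "support"])
    for (contig, strand), sub in reads.groupby(["contig", "strand"], sort=True):
        pos, counts = np.unique(sub["pos"].to_numpy(), return_counts=True)
        # split where the gap between consecutive covered bases exceeds merge_distance
        breaks = np.flatnonzero(np.diff(pos) > merge_distance) + 1
        for chunk_pos, chunk_cnt in zip(np.split(pos, breaks), np.split(counts, breaks)):
            support = int(chunk_cnt.sum())
            if support < min_reads:
                continue
            apex = int(chunk_pos[-1] if strand == "+" else chunk_pos[0])
            rows.append(dict(contig=contig, strand=strand,
                             start=int(chunk_pos[0]), end=int(chunk_pos[-1]) + 1,
                             apex=apex, support=support))
    out = pd.DataFrame(rows, columns=["contig", "strand", "start", "end", "apex", "support"])
    return out.sort_values(["contig", "strand", "start"]).reset_index(drop=True)


def extend_pas(apex: int, contig_length: int, flank: int = FLANK) -> Tuple[int, int]:
    """±flank comparison region around an apex, clipped to the contig."""
    return max(0, apex - flank), min(contig_length, apex + flank + 1)


# ---------------------------------------------------------------------------
# reciprocal mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappedRegion:
    contig: str
    start: int
    end: int
    flip: str           # '+' same strand, '-' inverted
    covered_fraction: float


def map_region(bm: BlockMap, contig: str, start: int, end: int,
               min_overlap_fraction: float = 0.9) -> Optional[MappedRegion]:
    """Project a region through a block map.

    The region maps when at least ``min_overlap_fraction`` of its bases fall in
    blocks pointing to a single (target contig, orientation); the projected
    span is the hull of the mapped pieces.  Returns None otherwise.
    """
    width = end - start
    if width <= 0:
        return None
    groups: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for b in bm.blocks_overlapping(contig, start, end):
        s, e = max(start, b.start_a), min(end, b.end_a)
        if b.strand == "+":
            piece = (b.start_b + (s - b.start_a), b.start_b + (e - b.start_a))
        else:
            piece = (b.end_b - (e - b.start_a), b.end_b - (s - b.start_a))
        groups.setdefault((b.contig_b, b.strand), []).append(piece)
    best = None
    for (tc, flip), pieces in groups.items():
        cov = sum(e - s for s, e in pieces)
        if best is None or cov > best[0]:
            best = (cov, tc, flip, pieces)
    if best is None:
        return None
    cov, tc, flip, pieces = best
    frac = cov / width
    if frac < min_overlap_fraction:
        return None
    return MappedRegion(tc, min(s for s, _ in pieces), max(e for _, e in pieces),
                        flip, frac)


def reciprocal_map(regions: pd.DataFrame, block_map_ab: BlockMap,
                   block_map_ba: BlockMap,
                   min_overlap_fraction: float = 0.9) -> pd.DataFrame:
    """Forward-project regions and verify they project back onto themselves.

    ``regions`` needs contig / start / end columns.  Adds status plus the
    projected target coordinates (NaN when unmapped) and the stage at which a
    failure occurred.
    """
    rows = []
    for r in regions.itertuples(index=False):
        fwd = map_region(block_map_ab, r.contig, r.start, r.end, min_overlap_fraction)
        if fwd is None:
            rows.append(dict(status=STATUS_UNMAPPED_FWD, target_contig=None,
                             target_start=np.nan, target_end=np.nan, flip=None))
            continue
        back = map_region(block_map_ba, fwd.contig, fwd.start, fwd.end,
                          min_overlap_fraction)
        ok = (back is not None and back.contig == r.contig
              and min(back.end, r.end) - max(back.start, r.start)
              >= min_overlap_fraction * (r.end - r.start))
        if not ok:
            rows.append(dict(status=STATUS_UNMAPPED_REV, target_contig=None,
                             target_start=np.nan, target_end=np.nan, flip=None))
            continue
        rows.append(dict(status=STATUS_RECIPROCAL, target_contig=fwd.contig,
                         target_start=fwd.start, target_end=fwd.end, flip=fwd.flip))
    mapped = pd.DataFrame(rows, index=regions.index)
    return pd.concat([regions.reset_index(drop=True), mapped.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# unified catalog
# ---------------------------------------------------------------------------

def _flip_strand(strand: str, flip: str) -> str:
    if flip == "+":
        return strand
    return "-" if strand == "+" else "+"


def _more_3prime(apexes: pd.Series, strand: str) -> int:
    """Index (label) of the most 3' apex for tie breaking."""
    return apexes.idxmax() if strand == "+" else apexes.idxmin()


def unify_pas(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, pair: GenomePair,
              flank: int = FLANK, min_overlap_fraction: float = 0.9) -> pd.DataFrame:
    """Merge per-species peaks into one cross-species PAS catalog.

    Reciprocally mapped A regions whose projected span overlaps a B peak
    region (≥1 bp, same contig and projected strand) become shared entries
    carrying both native apexes; a projected span overlapping several B peaks
    takes the one whose apex is nearest the projected A apex (tie: more 3').
    Unmatched reciprocal regions become single-origin entries quantifiable in
    the other species through the projection; regions failing reciprocity are
    kept with their failure stage and no cross-species coordinates.
    """
    len_a = {c: len(s) for c, s in pair.sequences_a.items()}
    len_b = {c: len(s) for c, s in pair.sequences_b.items()}

    def regions_of(peaks: pd.DataFrame, lens: Dict[str, int]) -> pd.DataFrame:
        spans = [extend_pas(a, lens[c], flank) for a, c in
                 zip(peaks["apex"], peaks["contig"])]
        out = peaks[["contig", "strand", "apex", "support"]].copy()
        out["start"] = [s for s, _ in spans]
        out["end"] = [e for _, e in spans]
        return out

    ra = regions_of(peaks_a, len_a) if len(peaks_a) else pd.DataFrame(
        columns=["contig", "strand", "apex", "support", "start", "end"])
    rb = regions_of(peaks_b, len_b) if len(peaks_b) else pd.DataFrame(
        columns=["contig", "strand", "apex", "support", "start", "end"])

    proj = reciprocal_map(ra[["contig", "start", "end"]], pair.block_map_ab,
                          pair.block_map_ba, min_overlap_fraction)
    rows: List[dict] = []
    matched_b: set = set()
    for i in range(len(ra)):
        a = ra.iloc[i]
        p = proj.iloc[i]
        row = dict(origin="a", status=p["status"],
                   contig_a=a["contig"], strand_a=a["strand"], apex_a=int(a["apex"]),
                   start_a=int(a["start"]), end_a=int(a["end"]),
                   contig_b=None, strand_b=None, apex_b=np.nan,
                   start_b=np.nan, end_b=np.nan, support_a=int(a["support"]),
                   support_b=0)
        if p["status"] == STATUS_RECIPROCAL:
            strand_b = _flip_strand(a["strand"], p["flip"])
            apex_map = pair.block_map_ab.map_position(a["contig"], int(a["apex"]))
            if apex_map is not None and apex_map[0] == p["target_contig"]:
                apex_b_proj = apex_map[1]
            else:
                apex_b_proj = int((p["target_start"] + p["target_end"]) // 2)
            cand = rb[(rb["contig"] == p["target_contig"]) & (rb["strand"] == strand_b)
                      & (rb["end"] > p["target_start"]) & (rb["start"] < p["target_end"])]
            cand = cand[[j not in matched_b for j in cand.index]]
            if len(cand):
                dist = (cand["apex"] - apex_b_proj).abs()
                nearest = dist[dist == dist.min()]
                if len(nearest) > 1:
                    j = _more_3prime(cand.loc[nearest.index, "apex"], strand_b)
                else:
                    j = nearest.index[0]
                b = rb.loc[j]
                matched_b.add(j)
                row.update(origin="both", contig_b=b["contig"], strand_b=b["strand"],
                           apex_b=int(b["apex"]), start_b=int(b["start"]),
                           end_b=int(b["end"]), support_b=int(b["support"]))
            else:
                s_b, e_b = extend_pas(apex_b_proj, len_b[p["target_contig"]], flank)
                row.update(contig_b=p["target_contig"], strand_b=strand_b,
                           apex_b=int(apex_b_proj), start_b=s_b, end_b=e_b)
        rows.append(row)

    leftover = rb[[j not in matched_b for j in rb.index]]
    if len(leftover):
        proj_b = reciprocal_map(leftover[["contig", "start", "end"]],
                                pair.block_map_ba, pair.block_map_ab,
                                min_overlap_fraction)
        for i in range(len(leftover)):
            b = leftover.iloc[i]
            p = proj_b.iloc[i]
            row = dict(origin="b", status=p["status"],
                       contig_a=None, strand_a=None, apex_a=np.nan,
                       start_a=np.nan, end_a=np.nan,
                       contig_b=b["contig"], strand_b=b["strand"], apex_b=int(b["apex"]),
                       start_b=int(b["start"]), end_b=int(b["end"]),
                       support_a=0, support_b=int(b["support"]))
            if p["status"] == STATUS_RECIPROCAL:
                strand_a = _flip_strand(b["strand"], p["flip"])
                apex_map = pair.block_map_ba.map_position(b["contig"], int(b["apex"]))
                if apex_map is not None and apex_map[0] == p["target_contig"]:
                    apex_a_proj = apex_map[1]
                else:
                    apex_a_proj = int((p["target_start"] + p["target_end"]) // 2)
                s_a, e_a = extend_pas(apex_a_proj, len_a[p["target_contig"]], flank)
                row.update(contig_a=p["target_contig"], strand_a=strand_a,
                           apex_a=int(apex_a_proj), start_a=s_a, end_a=e_a)
            rows.append(row)

    catalog = pd.DataFrame(rows)
    catalog = catalog.sort_values(
        ["contig_a", "strand_a", "apex_a", "contig_b", "apex_b"],
        na_position="last").reset_index(drop=True)
    catalog.insert(0, "pas_id", [f"pas{i:06d}" for i in range(len(catalog))])
    return catalog
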