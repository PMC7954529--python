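"""Sequence-level features of PAS regions.

Covers the polyadenylation signal-site hexamers (scanned in a fixed priority
order reflecting their genome-wide frequency), species-specific signal calls
restricted to the two usage-promoting motifs (AATAAA, ATTAAA), strand-aware
nucleotide content (U content read as T on the transcribed strand), the
AU-rich-element fraction of 3' UTRs, and mean per-base conservation scores
over the PAS region and three 200 bp flanking windows on each side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomes import revcomp

#: Hexamer priority: most common signal first; the scan returns the first hit.
SIGNAL_MOTIFS = ("AATAAA", "ATTAAA", "AAAAAG", "AAAAAA", "TATAAA", "AATATA",
                 "AGTAAA", "AATACA", "GATAAA", "AATAGA", "CATAAA", "ACTAAA")
TOP_TWO = ("AATAAA", "ATTAAA")

NONE_MOTIF = "none"


def region_sequence(genome: Dict[str, str], contig: str, start: int, end: int,
                    strand: str) -> str:
    """Strand-oriented (5'->3' on the transcript) sequence of a region."""
    seq = genome[contig][max(0, start):end].upper()
    return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class SignalSiteCall:
    motif: str               # chosen (highest-priority) motif or "none"
    all_found: Tuple[str, ...]


def scan_signal_sites(sequence: str) -> SignalSiteCall:
    """Find signal-site hexamers in a strand-oriented PAS region.

    All 12 motifs are searched; the call is the first present in priority
    order, independent of position or multiplicity within the region.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        return SignalSiteCall(NONE_MOTIF, ())
    found = tuple(m for m in SIGNAL_MOTIFS if m in seq)
    return SignalSiteCall(found[0] if found else NONE_MOTIF, found)


def species_specific_signal(call_a: SignalSiteCall, call_b: SignalSiteCall) -> str:
    """a_only / b_only / both / neither, counting only the top-two motifs.

    Only AATAAA and ATTAAA are associated with increased usage, so a PAS
    "has a signal site" here only when its chosen motif is one of those.
    """
    has_a = call_a.motif in TOP_TWO
    has_b = call_b.motif in TOP_TWO
    if has_a and has_b:
        return "both"
    if has_a:
        return "a_only"
    if has_b:
        return "b_only"
    return "neither"


def nucleotide_content(sequence: str, strand: str, base: str) -> float:
    """Proportion of ``base`` on the transcribed strand; Ns excluded entirely.

    ``sequence`` is the plus-strand genomic sequence; minus-strand regions are
    reverse-complemented before counting, so base="T" measures U content of
    the transcript.  Returns NaN for an empty (or all-N) region.
    """
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    seq = sequence.upper()
    if strand == "-":
        seq = revcomp(seq)
    seq = seq.replace("N", "")
    if not seq:
        return float("nan")
    return seq.count(base) / len(seq)


_ARE_RUN = re.compile(r"[AT]{5,}")


def are_fraction(utr3_sequence: str) -> float:
    """Fraction of the 3' UTR covered by A/U-only runs of length ≥5.

    Runs are maximal (the regex is greedy), so coverage never double counts.
    Returns NaN for an empty sequence.
    """
    seq = utr3_sequence.upper()
    if not seq:
        return float("nan")
    covered = sum(m.end() - m.start() for m in _ARE_RUN.finditer(seq))
    return covered / len(seq)


# ---------------------------------------------------------------------------
# conservation-score profiles
# ---------------------------------------------------------------------------

WINDOW_LABELS = ("u3", "u2", "u1", "pas", "d1", "d2", "d3")


def _window_mean(starts: np.ndarray, ends: np.ndarray, scores: np.ndarray,
                 lo: int, hi: int) -> float:
    """Mean score over [lo, hi); NaN unless every base has a score."""
    i = np.searchsorted(starts, lo, side="right") - 1
    if i < 0:
        i = 0
    total, covered = 0.0, 0
    while i < starts.size and starts[i] < hi:
        s, e = max(lo, starts[i]), min(hi, ends[i])
        if e > s:
            total += scores[i] * (e - s)
            covered += e - s
        i += 1
    if covered < hi - lo:
        return float("nan")
    return total / (hi - lo)


def region_score_profiles(track: Dict[str, pd.DataFrame], catalog: pd.DataFrame,
                          species: str = "a", window: int = 200,
                          n_flanks: int = 3) -> pd.DataFrame:
    """Mean score of the PAS window and ``n_flanks`` windows on each side.

    The layout tiles ``[apex − (n_flanks+0.5)·window, apex + (n_flanks+0.5)·window)``
    into 2·n_flanks+1 equal bins, labeled u3..u1 / pas / d1..d3 in
    transcription order (flipped for minus-strand PAS).  A window with any
    unscored base is NaN; ``complete`` marks rows with all windows scored.
    ``track`` maps contig to sorted (start, end, score) intervals, as read by
    :func:`apakit.io.read_bedgraph`; a contig absent from the track yields all
    NaN for its PAS.
    """
    apex_c, contig_c, strand_c = f"apex_{species}", f"contig_{species}", f"strand_{species}"
    half = window // 2
    labels = list(WINDOW_LABELS) if n_flanks == 3 else (
        [f"u{i}" for i in range(n_flanks, 0, -1)] + ["pas"]
        + [f"d{i}" for i in range(1, n_flanks + 1)])
    rows = []
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, df in track.items():
        arrays[contig] = (df["start"].to_numpy(), df["end"].to_numpy(),
                          df["score"].to_numpy(dtype=float))
    for r in catalog.dropna(subset=[apex_c]).itertuples(index=False):
        apex = int(getattr(r, apex_c))
        contig = getattr(r, contig_c)
        strand = getattr(r, strand_c)
        vals: List[float] = []
        if contig in arrays:
            starts, ends, scores = arrays[contig]
            for k in range(-n_flanks, n_flanks + 1):
                lo = apex - half + k * window
                vals.append(_window_mean(starts, ends, scores, lo, lo + window))
        else:
            vals = [float("nan")] * (2 * n_flanks + 1)
        if strand == "-":
            vals = vals[::-1]
        row = dict(pas_id=r.pas_id, **dict(zip(labels, vals)))
        row["complete"] = bool(np.all(np.isfinite(vals)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["pas_id", *labels, "complete"])
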