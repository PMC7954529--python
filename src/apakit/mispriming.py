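"""Internal-priming (mispriming) filter for 3'-Seq read ends.

The oligo-dT primer of 3'-Seq can anneal to genomic adenine stretches instead
of a true poly(A) tail.  Such artifact reads are recognized by the genomic
sequence the primer would have bound: the 10 bases past the read's 3' end in
the direction of transcription.  A read is removed when that window contains
six consecutive adenines or at least 7 of its 10 bases are adenine; ambiguous
(N) bases count as adenine so assembly quality cannot hide an A-stretch.

Classification is a pure function of the 10-mer, so the filter is idempotent
and strand handling lives entirely in the window extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .genomes import revcomp

WINDOW = 10
MIN_A_COUNT = 7
RUN_LENGTH = 6

REASON_NONE = "none"
REASON_RUN = "six_consecutive_A"
REASON_COUNT = "seven_of_ten_A"
REASON_BOUNDARY = "boundary"


@dataclass(frozen=True)
class MisprimingCall:
    upstream_10mer: str
    reason: str


@dataclass
class FilterStats:
    """Counts per reason per sample; kept + removed == input."""

    per_sample: pd.DataFrame  # index sample, columns kept/six_consecutive_A/seven_of_ten_A/boundary

    @property
    def total_kept(self) -> int:
        return int(self.per_sample["kept"].sum())

    @property
    def total_removed(self) -> int:
        cols = [REASON_RUN, REASON_COUNT, REASON_BOUNDARY]
        return int(self.per_sample[cols].to_numpy().sum())


def is_misprimed(tenmer: str) -> str:
    """Classify a 10-mer: six_consecutive_A beats seven_of_ten_A beats none."""
    if len(tenmer) != WINDOW:
        raise ValueError(f"expected a {WINDOW}-mer, got {len(tenmer)} bases")
    t = tenmer.upper()
    if any(c not in "ACGT" for c in t):
        raise ValueError(f"bad alphabet in {tenmer!r}; substitute N->A first")
    if "A" * RUN_LENGTH in t:
        return REASON_RUN
    if t.count("A") >= MIN_A_COUNT:
        return REASON_COUNT
    return REASON_NONE


def upstream_window(genome: Dict[str, str], contig: str, pos: int, strand: str,
                    window: int = WINDOW) -> MisprimingCall:
    """Extract the A-rich-test window for one read and classify it.

    ``pos`` is the 0-based coordinate of the read's 3'-most aligned base.  The
    window is the `window` bases past that base along the read strand (where
    the poly(A) tail, or a genomic A-stretch, sits); minus-strand windows are
    reverse-complemented so the test always reads 5'->3' on the transcript.
    """
    seq = genome.get(contig)
    if seq is None:
        raise KeyError(f"contig {contig!r} absent from genome")
    if strand == "+":
        lo, hi = pos + 1, pos + 1 + window
        if hi > len(seq):
            return MisprimingCall("", REASON_BOUNDARY)
        w = seq[lo:hi].upper()
    else:
        lo, hi = pos - window, pos
        if lo < 0:
            return MisprimingCall("", REASON_BOUNDARY)
        w = revcomp(seq[lo:hi].upper())
    w = w.replace("N", "A")
    return MisprimingCall(w, is_misprimed(w))


def _contig_arrays(genome: Dict[str, str]) -> Dict[str, np.ndarray]:
    return {name: np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            for name, seq in genome.items()}


_A, _T = ord("A"), ord("T")
_N = ord("N")


def _classify_windows(seq: np.ndarray, pos: np.ndarray, strand_plus: bool) -> np.ndarray:
    """Vectorized window classification; returns reason codes per read.

    Codes: 0 none, 1 six_consecutive_A, 2 seven_of_ten_A, 3 boundary.
    """
    n = len(pos)
    out = np.zeros(n, dtype=np.int8)
    if n == 0:
        return out
    L = len(seq)
    if strand_plus:
        ok = pos + 1 + WINDOW <= L
        base_idx = pos + 1
        offsets = np.arange(WINDOW)
        target = _A
    else:
        ok = pos - WINDOW >= 0
        base_idx = pos - WINDOW
        offsets = np.arange(WINDOW)
        target = _T  # A on the transcript strand is T on the reference
    out[~ok] = 3
    if not ok.any():
        return out
    idx = base_idx[ok, None] + offsets[None, :]
    chars = seq[idx]
    is_a = (chars == target) | (chars == _N)  # N counts as adenine
    counts = is_a.sum(axis=1)
    # a run of RUN_LENGTH anywhere in the 10-mer
    run = np.zeros(is_a.shape[0], dtype=bool)
    for start in range(WINDOW - RUN_LENGTH + 1):
        run |= is_a[:, start:start + RUN_LENGTH].all(axis=1)
    codes = np.zeros(is_a.shape[0], dtype=np.int8)
    codes[counts >= MIN_A_COUNT] = 2
    codes[run] = 1
    out[ok] = codes
    return out


_CODE_TO_REASON = {0: REASON_NONE, 1: REASON_RUN, 2: REASON_COUNT, 3: REASON_BOUNDARY}


def classify_reads(reads: pd.DataFrame, genome: Dict[str, str]) -> pd.Series:
    """Reason label per read for a (contig, pos, strand) frame."""
    missing = set(reads["contig"].unique()) - set(genome)
    if missing:
        raise KeyError(f"contigs absent from genome: {sorted(missing)}")
    arrays = _contig_arrays(genome)
    codes = np.zeros(len(reads), dtype=np.int8)
    pos_all = reads["pos"].to_numpy()
    groups = reads.groupby(["contig", "strand"], sort=False).indices
    for (contig, strand), ii in groups.items():
        codes[ii] = _classify_windows(arrays[contig], pos_all[ii], strand == "+")
    return pd.Series([_CODE_TO_REASON[c] for c in codes], index=reads.index, name="reason")


def filter_reads(reads: pd.DataFrame, genome: Dict[str, str],
                 sample_col: str = "sample") -> Tuple[pd.DataFrame, FilterStats]:
    """Drop reads whose upstream window fires the A-rich rule.

    Boundary-window reads are discarded too (cannot be certified artifact
    free).  Returns the kept reads and per-sample reason counts.
    """
    reason = classify_reads(reads, genome)
    kept = reads.loc[reason == REASON_NONE].copy()
    samples = reads[sample_col] if sample_col in reads.columns else pd.Series("all", index=reads.index)
    tab = pd.crosstab(samples, reason)
    for col in (REASON_NONE, REASON_RUN, REASON_COUNT, REASON_BOUNDARY):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab.rename(columns={REASON_NONE: "kept"})
    tab = tab[["kept", REASON_RUN, REASON_COUNT, REASON_BOUNDARY]]
    return kept, FilterStats(per_sample=tab)
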