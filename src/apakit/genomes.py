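"""Two-genome container and block-based coordinate projection.

A :class:`GenomePair` holds the sequences of two species plus an ordered set of
alignment blocks relating them, the synthetic stand-in for a pair of reference
assemblies and their liftover chains.  Blocks are half-open, equal length on
both sides, and non-overlapping within each genome; composing the forward and
reverse maps on any position inside a reciprocal block is the identity.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Block:
    """One alignment block: [start_a, end_a) on A maps to [start_b, end_b) on B.

    ``strand`` is '+' when the block is colinear and '-' when genome B carries
    the reverse complement, in which case position start_a maps to end_b - 1.
    """

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    strand: str = "+"

    def __post_init__(self):
        if self.end_a - self.start_a != self.end_b - self.start_b:
            raise ValueError("block sides differ in length")
        if self.strand not in "+-":
            raise ValueError(f"bad block strand {self.strand!r}")

    def map_position(self, pos: int) -> Tuple[str, int, str]:
        off = pos - self.start_a
        if self.strand == "+":
            return self.contig_b, self.start_b + off, "+"
        return self.contig_b, self.end_b - 1 - off, "-"

    def flipped(self) -> "Block":
        """The same block viewed from genome B."""
        return Block(self.contig_b, self.start_b, self.end_b,
                     self.contig_a, self.start_a, self.end_a, self.strand)


class BlockMap:
    """Ordered non-overlapping blocks from a source genome to a target.

    Lookup is by binary search over per-contig sorted block starts.
    """

    def __init__(self, blocks: List[Block]):
        self.blocks = list(blocks)
        self._by_contig: Dict[str, Tuple[List[int], List[Block]]] = {}
        per: Dict[str, List[Block]] = {}
        for b in self.blocks:
            per.setdefault(b.contig_a, []).append(b)
        for contig, bl in per.items():
            bl.sort(key=lambda b: b.start_a)
            for prev, cur in zip(bl, bl[1:]):
                if cur.start_a < prev.end_a:
                    raise ValueError(f"overlapping blocks on {contig}")
            self._by_contig[contig] = ([b.start_a for b in bl], bl)

    def __len__(self) -> int:
        return len(self.blocks)

    def block_at(self, contig: str, pos: int) -> Optional[Block]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, bl = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < bl[i].end_a:
            return bl[i]
        return None

    def map_position(self, contig: str, pos: int) -> Optional[Tuple[str, int, str]]:
        """Project a single position, or None if it falls outside all blocks."""
        b = self.block_at(contig, pos)
        return None if b is None else b.map_position(pos)

    def blocks_overlapping(self, contig: str, start: int, end: int) -> List[Block]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return []
        starts, bl = entry
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            i = 0
        out = []
        while i < len(bl) and bl[i].start_a < end:
            if bl[i].end_a > start:
                out.append(bl[i])
            i += 1
        return out

    def inverted(self) -> "BlockMap":
        return BlockMap([b.flipped() for b in self.blocks])


@dataclass
class GenomePair:
    """Sequences of species A and B plus reciprocal block maps."""

    sequences_a: Dict[str, str]
    sequences_b: Dict[str, str]
    block_map_ab: BlockMap
    block_map_ba: BlockMap = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.block_map_ba is None:
            self.block_map_ba = self.block_map_ab.inverted()

    def sequences(self, species: str) -> Dict[str, str]:
        if species == "a":
            return self.sequences_a
        if species == "b":
            return self.sequences_b
        raise ValueError(f"unknown species {species!r}")

    def contig_length(self, species: str, contig: str) -> int:
        return len(self.sequences(species)[contig])
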