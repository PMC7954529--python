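"""Plain-text genomics I/O: FASTA, BED6 read ends, block maps, bedGraph.

BED and bedGraph are 0-based half-open natively.  Read 3'-ends travel as
one-bp BED6 intervals (name=sample, score=0).
"""

from __future__ import annotations

import textwrap
from typing import Dict, List

import pandas as pd
from pyfaidx import Fasta

from .genomes import Block, BlockMap

BLOCKMAP_COLUMNS = ["contig_a", "start_a", "end_a", "contig_b", "start_b", "end_b", "strand"]


def write_fasta(sequences: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, width) + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True, build_index=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_reads_bed(reads: pd.DataFrame, path: str, sample: str) -> None:
    """Write read 3'-end positions as 1-bp BED6 records."""
    df = pd.DataFrame({
        "contig": reads["contig"],
        "start": reads["pos"],
        "end": reads["pos"] + 1,
        "name": sample,
        "score": 0,
        "strand": reads["strand"],
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "name", "score", "strand"],
                     dtype={"contig": str, "name": str, "strand": str})
    if ((df["end"] - df["start"]) != 1).any():
        raise ValueError(f"{path}: read records must be 1-bp intervals")
    return pd.DataFrame({"contig": df["contig"], "pos": df["start"], "strand": df["strand"]})


def write_block_map(bm: BlockMap, path: str) -> None:
    rows = [[b.contig_a, b.start_a, b.end_a, b.contig_b, b.start_b, b.end_b, b.strand]
            for b in bm.blocks]
    pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_block_map(path: str) -> BlockMap:
    df = pd.read_csv(path, sep="\t", dtype={"contig_a": str, "contig_b": str, "strand": str})
    missing = set(BLOCKMAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: block map missing columns {sorted(missing)}")
    blocks: List[Block] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            blocks.append(Block(row.contig_a, int(row.start_a), int(row.end_a),
                                row.contig_b, int(row.start_b), int(row.end_b), row.strand))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed block map row: {exc}") from exc
    return BlockMap(blocks)


def read_bedgraph(path: str) -> Dict[str, pd.DataFrame]:
    """Per-contig score intervals, sorted by start.

    Returns contig -> DataFrame(start, end, score).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "score"], dtype={"contig": str})
    return {contig: sub[["start", "end", "score"]].sort_values("start").reset_index(drop=True)
            for contig, sub in df.groupby("contig")}
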