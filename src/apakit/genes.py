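"""Gene models and GFF3 serialization.

All coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted at the I/O boundary.  Only the five feature types this
pipeline consumes are represented: gene, exon, CDS, five_prime_UTR,
three_prime_UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

Interval = Tuple[int, int]


def _merge_sorted(ivals: List[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(self, name, sorted(getattr(self, name)))

    @property
    def introns(self) -> List[Interval]:
        ex = _merge_sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]

    def tx_end(self) -> int:
        """Position of the transcript 3' end (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def downstream_interval(self, window: int = 5000, contig_length: int | None = None) -> Interval:
        """Half-open genomic interval covering `window` bp past the 3' end."""
        if self.strand == "+":
            s, e = self.end, self.end + window
        else:
            s, e = self.start - window, self.start
        if contig_length is not None:
            s, e = max(0, s), min(contig_length, e)
        return max(0, s), e


def write_gff3(genes: List[GeneModel], path: str) -> None:
    rows = []
    for g in genes:
        rows.append((g.contig, "apakit", "gene", g.start + 1, g.end, ".",
                     g.strand, ".", f"ID={g.gene_id}"))
        for ftype, ivals in (("exon", g.exons), ("CDS", g.cds),
                             ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
            for s, e in ivals:
                rows.append((g.contig, "apakit", ftype, s + 1, e, ".",
                             g.strand, ".", f"Parent={g.gene_id}"))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_gff3(path: str) -> List[GeneModel]:
    genes: Dict[str, GeneModel] = {}
    order: List[str] = []
    pending: List[Tuple[str, str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, _src, ftype, s1, e1, _sc, strand, _fr, attrs = line.rstrip("\n").split("\t")
            start, end = int(s1) - 1, int(e1)
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = GeneModel(gid, contig, strand, start, end)
                order.append(gid)
            else:
                pending.append((fields["Parent"], ftype, start, end))
    for gid, ftype, start, end in pending:
        g = genes[gid]
        attr = {"exon": "exons", "CDS": "cds",
                "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
        getattr(g, attr).append((start, end))
    for g in genes.values():
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(g, name, sorted(getattr(g, name)))
    return [genes[g] for g in order]
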