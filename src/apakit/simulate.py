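"""Synthetic two-species APA world: genomes, genes, planted truth, 3'-Seq reads.

The generator emulates the statistical structure of a human/chimpanzee 3'-Seq
comparison: two genomes related by per-base substitutions and block
rearrangements, genes carrying 1-8 polyadenylation sites whose per-species
usage vectors are Dirichlet-distributed, a planted subset of genes with usage
shifts of at least a configured |dPAU|, species-specific sites with zero usage
in the other species, hexamer signal sites written 10-30 bp upstream of each
apex, and a configurable rate of internal-priming artifact reads sampled from
genomic loci that genuinely satisfy the A-rich filter rule.

Everything is deterministic given the seed; write/read round-trips are exact.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as akio
from .genes import GeneModel, write_gff3, read_gff3
from .genomes import Block, BlockMap, GenomePair

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T, _N = (ord(c) for c in "ACGTN")

LOCATIONS = ("utr3", "intron", "cds", "utr5", "end")
DEFAULT_LOCATION_PROBS = (0.40, 0.32, 0.10, 0.05, 0.13)
#: P(gene has k PAS), k = 1..8; mean ~3.3 sites/gene
DEFAULT_PAS_PER_GENE = (0.18, 0.22, 0.18, 0.13, 0.10, 0.08, 0.06, 0.05)
MOTIF_CHOICES = ("AATAAA", "ATTAAA", "none")
DEFAULT_MOTIF_PROBS = (0.70, 0.15, 0.15)

MIN_PAS_SPACING = 250  # keeps ±100 bp PAS regions disjoint within a gene


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

def generate_genome_pair(n_contigs: int = 1, contig_length: int = 100_000,
                         divergence_rate: float = 0.01,
                         n_rearranged_blocks: int = 0,
                         seed: int = 0) -> GenomePair:
    """Random genome A; genome B = substitutions + block shuffle of A.

    Rearrangement partitions each contig into equal blocks and permutes their
    order in genome B; the block map records the correspondence.  With zero
    divergence and zero rearranged blocks the genomes are identical under an
    identity map.
    """
    if n_contigs <= 0 or contig_length <= 0:
        raise ValueError("n_contigs and contig_length must be positive")
    if contig_length < 10_000:
        raise ValueError("contig_length must be at least 10 kb")
    if not 0.0 <= divergence_rate <= 0.1:
        raise ValueError("divergence_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    seqs_a: Dict[str, str] = {}
    seqs_b: Dict[str, str] = {}
    blocks: List[Block] = []
    blocks_per_contig = max(1, int(np.ceil(n_rearranged_blocks / n_contigs))) \
        if n_rearranged_blocks > 0 else 1
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        arr_a = rng.choice(BASES, size=contig_length)
        # substitutions: force a different base at selected positions
        arr_b = arr_a.copy()
        if divergence_rate > 0:
            hit = rng.random(contig_length) < divergence_rate
            idx = np.flatnonzero(hit)
            shift = rng.integers(1, 4, size=idx.size)
            arr_b[idx] = BASES[(np.searchsorted(BASES, arr_a[idx]) + shift) % 4]
        bounds = np.linspace(0, contig_length, blocks_per_contig + 1).astype(int)
        order = rng.permutation(blocks_per_contig) if blocks_per_contig > 1 \
            else np.array([0])
        pieces = []
        pos_b = 0
        for bi in order:
            sa, ea = int(bounds[bi]), int(bounds[bi + 1])
            length = ea - sa
            blocks.append(Block(name, sa, ea, name, pos_b, pos_b + length, "+"))
            pieces.append(arr_b[sa:ea])
            pos_b += length
        seqs_a[name] = arr_a.tobytes().decode()
        seqs_b[name] = np.concatenate(pieces).tobytes().decode()
    return GenomePair(seqs_a, seqs_b, BlockMap(blocks))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

# transcription-order part lengths: utr5, cds, intron, cds, utr3
GENE_PARTS = (300, 400, 1500, 500, 1800)
GENE_LENGTH = sum(GENE_PARTS)          # 4500
DOWNSTREAM = 5000
GENE_SLOT = GENE_LENGTH + DOWNSTREAM + 1000   # footprint incl. intergenic gap


def _build_gene(gene_id: str, contig: str, strand: str, start: int) -> GeneModel:
    u5, c1, intr, c2, u3 = GENE_PARTS
    end = start + GENE_LENGTH
    if strand == "+":
        utr5 = [(start, start + u5)]
        cds = [(start + u5, start + u5 + c1), (start + u5 + c1 + intr, start + u5 + c1 + intr + c2)]
        utr3 = [(start + u5 + c1 + intr + c2, end)]
        exons = [(start, start + u5 + c1), (start + u5 + c1 + intr, end)]
    else:
        utr5 = [(end - u5, end)]
        cds = [(end - u5 - c1, end - u5), (start + u3, start + u3 + c2)]
        utr3 = [(start, start + u3)]
        exons = [(start, start + u3 + c2), (end - u5 - c1, end)]
    return GeneModel(gene_id, contig, strand, start, end,
                     exons=exons, cds=cds, utr5=utr5, utr3=utr3)


def generate_gene_models(pair: GenomePair, n_genes: int, seed: int = 0) -> List[GeneModel]:
    """Place genes inside alignment blocks of genome A, never straddling one.

    Each gene occupies a fixed-layout slot (5' UTR / CDS / intron / CDS /
    3' UTR plus 5 kb of free downstream space) so every genic PAS category has
    room for planted sites.  Strands alternate deterministically.
    """
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    gi = 0
    for block in pair.block_map_ab.blocks:
        lo, hi = block.start_a + 200, block.end_a - 200
        pos = lo
        while pos + GENE_SLOT <= hi and gi < n_genes:
            strand = "+" if rng.random() < 0.5 else "-"
            # leave the 5 kb downstream window inside the slot on the 3' side
            gstart = pos if strand == "+" else pos + DOWNSTREAM
            genes.append(_build_gene(f"g{gi:05d}", block.contig_a, strand, gstart))
            gi += 1
            pos += GENE_SLOT
        if gi >= n_genes:
            break
    if gi < n_genes:
        raise ValueError(
            f"genome too small: placed {gi} of {n_genes} genes; "
            f"need ~{n_genes * GENE_SLOT} bp of block space")
    return genes


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class ApaTruth:
    """Planted ground truth: one row per PAS plus per-gene metadata.

    ``pas`` columns: pas_id, gene_id, contig, strand, apex_a, apex_b, strand_b,
    location, usage_a, usage_b, true_dpau, divergent, species_specific,
    motif_a, motif_b.  ``genes`` columns: gene_id, expression, n_pas,
    divergent_gene.
    """

    pas: pd.DataFrame
    genes: pd.DataFrame

    def usage_matrix(self, species: str) -> pd.Series:
        return self.pas.set_index("pas_id")[f"usage_{species}"]


def _category_intervals(g: GeneModel, contig_length: int) -> Dict[str, List[Tuple[int, int]]]:
    return {
        "utr3": list(g.utr3),
        "intron": list(g.introns),
        "cds": list(g.cds),
        "utr5": list(g.utr5),
        "end": [g.downstream_interval(DOWNSTREAM, contig_length)],
    }


def plant_apa_truth(gene_models: Sequence[GeneModel],
                    pair: GenomePair,
                    pas_per_gene_distribution: Sequence[float] = DEFAULT_PAS_PER_GENE,
                    location_probs: Sequence[float] = DEFAULT_LOCATION_PROBS,
                    divergent_fraction: float = 0.2,
                    min_true_dpau: float = 0.2,
                    max_true_dpau: float = 0.4,
                    species_specific_fraction: float = 0.02,
                    motif_probs: Sequence[float] = DEFAULT_MOTIF_PROBS,
                    motif_discordance: float = 0.03,
                    dirichlet_alpha: float = 0.9,
                    seed: int = 0) -> ApaTruth:
    """Plant PAS apexes, usage vectors, divergence and signal-site motifs.

    Usage vectors are Dirichlet(alpha) draws shared between species; in a
    ``divergent_fraction`` of multi-PAS genes a usage mass of
    U(min_true_dpau, max_true_dpau) is transferred between two sites in
    species B.  Species-specific PAS get usage exactly 0 in the other species.
    Signal-site hexamers are written into both genome sequences 10-30 bp
    upstream of each apex (in transcription direction), so sequence-level
    analyses see real motifs at mapped orthologous positions.
    """
    for frac in (divergent_fraction, species_specific_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    if not np.isclose(sum(pas_per_gene_distribution), 1.0):
        raise ValueError("pas_per_gene_distribution must sum to 1")
    rng = np.random.default_rng(seed)
    loc_p = np.asarray(location_probs, dtype=float)
    loc_p = loc_p / loc_p.sum()

    seq_a = {c: bytearray(s.encode()) for c, s in pair.sequences_a.items()}
    seq_b = {c: bytearray(s.encode()) for c, s in pair.sequences_b.items()}

    pas_rows: List[dict] = []
    gene_rows: List[dict] = []
    for g in gene_models:
        clen = pair.contig_length("a", g.contig)
        n_pas = 1 + int(rng.choice(len(pas_per_gene_distribution),
                                   p=pas_per_gene_distribution))
        cats = rng.choice(len(LOCATIONS), size=n_pas, p=loc_p)
        intervals = _category_intervals(g, clen)
        apexes: List[Tuple[int, str]] = []   # (apex, location)
        taken: List[int] = []
        for cat_i in cats:
            loc = LOCATIONS[cat_i]
            placed = False
            ivs = intervals[loc]
            if not ivs:
                continue    # gene lacks this feature class; skip this PAS
            for _ in range(50):
                s, e = ivs[int(rng.integers(len(ivs)))]
                s, e = s + 40, e - 40          # margin for motif planting
                if e <= s:
                    break
                apex = int(rng.integers(s, e))
                if all(abs(apex - t) >= MIN_PAS_SPACING for t in taken):
                    apexes.append((apex, loc))
                    taken.append(apex)
                    placed = True
                    break
            if not placed:
                continue
        if not apexes:
            warnings.warn(f"gene {g.gene_id} too short to host any PAS; skipped")
            continue
        k = len(apexes)
        usage_a = rng.dirichlet(np.full(k, dirichlet_alpha))
        usage_b = usage_a.copy()
        divergent = np.zeros(k, dtype=bool)
        true_dpau = np.zeros(k)
        sspec = np.array(["none"] * k, dtype=object)

        is_div_gene = k >= 2 and rng.random() < divergent_fraction
        if is_div_gene:
            delta = float(rng.uniform(min_true_dpau, max_true_dpau)) \
                if max_true_dpau > min_true_dpau else min_true_dpau
            i, j = int(np.argmax(usage_a)), int(np.argmin(usage_a))
            if i != j and usage_a[i] >= delta + 0.02:
                usage_b[i] -= delta
                usage_b[j] += delta
                if rng.random() < 0.5:       # random sign of the shift
                    usage_a, usage_b = usage_b.copy(), usage_a.copy()
                divergent[[i, j]] = True
                true_dpau = usage_a - usage_b
            else:
                is_div_gene = False
        elif k >= 2 and rng.random() < species_specific_fraction * k:
            cand = [x for x in range(k) if usage_a[x] >= 0.10]
            if cand:
                x = int(rng.choice(cand))
                sp = "a" if rng.random() < 0.5 else "b"
                if sp == "a":
                    usage_b[x] = 0.0
                    usage_b = usage_b / usage_b.sum()
                else:
                    usage_a[x] = 0.0
                    usage_a = usage_a / usage_a.sum()
                sspec[x] = sp
                true_dpau = usage_a - usage_b

        usage_a = usage_a / usage_a.sum()
        usage_b = usage_b / usage_b.sum()

        for x, (apex, loc) in enumerate(apexes):
            mapped = pair.block_map_ab.map_position(g.contig, apex)
            if mapped is None:
                continue   # cannot happen with genes placed inside blocks
            contig_b, apex_b, flip = mapped
            strand_b = g.strand if flip == "+" else ("-" if g.strand == "+" else "+")
            motif_a = str(rng.choice(MOTIF_CHOICES, p=np.asarray(motif_probs)))
            if sspec[x] != "none":
                # absent-species motif biased toward loss of the signal site
                other = str(rng.choice(MOTIF_CHOICES, p=np.array([0.2, 0.1, 0.7])))
                motif_b = other if sspec[x] == "a" else motif_a
                if sspec[x] == "b":
                    motif_a, motif_b = other, motif_a
            elif rng.random() < motif_discordance:
                motif_b = str(rng.choice(MOTIF_CHOICES, p=np.asarray(motif_probs)))
            else:
                motif_b = motif_a
            offset = int(rng.integers(10, 31))
            _write_motif(seq_a[g.contig], apex, g.strand, offset, motif_a)
            _write_motif(seq_b[contig_b], apex_b, strand_b, offset, motif_b)
            pas_rows.append(dict(
                pas_id=f"{g.gene_id}.p{x}", gene_id=g.gene_id, contig=g.contig,
                strand=g.strand, apex_a=apex, apex_b=apex_b, contig_b=contig_b,
                strand_b=strand_b, location=loc,
                usage_a=float(usage_a[x]), usage_b=float(usage_b[x]),
                true_dpau=float(true_dpau[x]), divergent=bool(divergent[x]),
                species_specific=sspec[x], motif_a=motif_a, motif_b=motif_b))
        expression = float(rng.lognormal(mean=np.log(200.0), sigma=1.0))
        gene_rows.append(dict(gene_id=g.gene_id, expression=expression,
                              n_pas=len(apexes), divergent_gene=bool(is_div_gene)))

    pair.sequences_a = {c: bytes(b).decode() for c, b in seq_a.items()}
    pair.sequences_b = {c: bytes(b).decode() for c, b in seq_b.items()}
    pas = pd.DataFrame(pas_rows)
    genes = pd.DataFrame(gene_rows)
    return ApaTruth(pas=pas, genes=genes)


def _write_motif(seq: bytearray, apex: int, strand: str, offset: int, motif: str) -> None:
    """Write a hexamer ending `offset` bp upstream of the apex (tx direction)."""
    if motif == "none":
        return
    from .genomes import revcomp
    if strand == "+":
        s = apex - offset - len(motif)
        if s < 0:
            return
        seq[s:s + len(motif)] = motif.encode()
    else:
        s = apex + offset
        if s + len(motif) > len(seq):
            return
        seq[s:s + len(motif)] = revcomp(motif).encode()


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """3'-end positions of one sample's reads with synthetic provenance."""

    sample_id: str
    species: str
    fraction: str
    reads: pd.DataFrame  # contig, pos, strand, provenance


def build_misprime_index(sequences: Dict[str, str]) -> pd.DataFrame:
    """All (contig, pos, strand) read placements whose upstream window fires.

    Mirrors the filter rule exactly: the 10 bases past a read end on its
    strand contain AAAAAA or >=7 adenines (N counting as A).
    """
    from .mispriming import WINDOW, MIN_A_COUNT, RUN_LENGTH
    frames = []
    for contig, s in sequences.items():
        arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        L = arr.size
        if L < WINDOW + 1:
            continue
        for strand in "+-":
            if strand == "+":
                base = (arr == _A) | (arr == _N)
            else:
                base = (arr == _T) | (arr == _N)
            cs = np.concatenate([[0], np.cumsum(base)])
            w = np.arange(0, L - WINDOW + 1)
            counts = cs[w + WINDOW] - cs[w]
            run_start = np.convolve(base.astype(np.int8), np.ones(RUN_LENGTH, dtype=np.int8),
                                    mode="valid") == RUN_LENGTH
            has_run = np.convolve(run_start.astype(np.int8),
                                  np.ones(WINDOW - RUN_LENGTH + 1, dtype=np.int8),
                                  mode="valid") > 0
            fires = (counts[: has_run.size] >= MIN_A_COUNT) | has_run
            ws = np.flatnonzero(fires)
            if strand == "+":
                pos = ws - 1
                pos = pos[pos >= 0]
            else:
                pos = ws + WINDOW
                pos = pos[pos <= L - 1]
            if pos.size:
                frames.append(pd.DataFrame({"contig": contig, "pos": pos, "strand": strand}))
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand"])
    return pd.concat(frames, ignore_index=True)


def _jitter(rng: np.random.Generator, n: int, max_abs: int = 5, p: float = 0.5) -> np.ndarray:
    """Symmetric geometric(p) offsets truncated at ±max_abs."""
    mag = np.minimum(rng.geometric(p, size=n) - 1, max_abs)
    sign = rng.choice([-1, 1], size=n)
    return mag * sign


def simulate_reads(pair: GenomePair, truth: ApaTruth,
                   samples_per_species: Tuple[int, int] = (5, 6),
                   reads_per_sample: int = 100_000,
                   mispriming_rate: float = 0.02,
                   jitter_max: int = 5,
                   fraction: str = "nuclear",
                   seed: int = 0) -> List[ReadSet]:
    """Simulate per-sample read 3'-ends around planted apexes plus artifacts.

    Genes are chosen proportional to their planted expression, the PAS within
    a gene by the species usage vector, and positions get geometric jitter.
    Misprimed reads land uniformly on precomputed A-rich loci and are labeled
    ``misprimed`` in the provenance column.
    """
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if not 0.0 <= mispriming_rate <= 0.5:
        raise ValueError("mispriming_rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out: List[ReadSet] = []
    expr = truth.genes.set_index("gene_id")["expression"]
    for species, n_samples in zip("ab", samples_per_species):
        pas = truth.pas
        usage_col = f"usage_{species}"
        if species == "a":
            contig_c, apex_c, strand_c = "contig", "apex_a", "strand"
        else:
            contig_c, apex_c, strand_c = "contig_b", "apex_b", "strand_b"
        # per-read PAS probabilities: gene weight x within-gene usage
        gene_w = expr.reindex(pas["gene_id"]).to_numpy()
        probs = gene_w * pas[usage_col].to_numpy()
        probs = probs / probs.sum()
        seqs = pair.sequences(species)
        clen = {c: len(s) for c, s in seqs.items()}
        mis_index = None
        if mispriming_rate > 0:
            mis_index = build_misprime_index(seqs)
            if mis_index.empty:
                raise ValueError(f"genome {species} has no A-rich locus; "
                                 "cannot simulate mispriming")
        for si in range(n_samples):
            sample_id = f"{species}{si + 1}"
            n_mis = int(rng.binomial(reads_per_sample, mispriming_rate))
            n_true = reads_per_sample - n_mis
            counts = rng.multinomial(n_true, probs)
            idx = np.repeat(np.arange(len(pas)), counts)
            pos = pas[apex_c].to_numpy()[idx] + _jitter(rng, idx.size, jitter_max)
            contigs = pas[contig_c].to_numpy()[idx]
            if idx.size:
                lens = pd.Series(contigs).map(clen).to_numpy()
                pos = np.clip(pos, 0, np.maximum(lens - 1, 0)).astype(int)
            df_true = pd.DataFrame({
                "contig": contigs,
                "pos": pos,
                "strand": pas[strand_c].to_numpy()[idx],
                "provenance": pas["pas_id"].to_numpy()[idx],
            })
            parts = [df_true]
            if n_mis > 0:
                pick = rng.integers(0, len(mis_index), size=n_mis)
                mdf = mis_index.iloc[pick].reset_index(drop=True)
                mdf["provenance"] = "misprimed"
                parts.append(mdf)
            reads = pd.concat(parts, ignore_index=True)
            reads["sample"] = sample_id
            out.append(ReadSet(sample_id, species, fraction, reads))
    return out


# ---------------------------------------------------------------------------
# dataset bundle and disk round trip
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All generator knobs; hashing the sorted fields fingerprints a dataset."""

    n_contigs: int = 2
    contig_length: int = 100_000
    divergence_rate: float = 0.01
    n_rearranged_blocks: int = 4
    n_genes: int = 15
    pas_per_gene_distribution: Tuple[float, ...] = DEFAULT_PAS_PER_GENE
    location_probs: Tuple[float, ...] = DEFAULT_LOCATION_PROBS
    divergent_fraction: float = 0.2
    min_true_dpau: float = 0.2
    max_true_dpau: float = 0.4
    species_specific_fraction: float = 0.02
    motif_discordance: float = 0.03
    dirichlet_alpha: float = 0.9
    samples_per_species: Tuple[int, int] = (5, 6)
    reads_per_sample: int = 20_000
    mispriming_rate: float = 0.02
    jitter_max: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedDataset:
    config: SimConfig
    pair: GenomePair
    genes: List[GeneModel]
    truth: ApaTruth
    read_sets: List[ReadSet]

    def reads_frame(self) -> pd.DataFrame:
        """All reads of all samples in one frame with sample/species columns."""
        frames = []
        for rs in self.read_sets:
            df = rs.reads.copy()
            df["sample"] = rs.sample_id
            df["species"] = rs.species
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator chain deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    s_genome, s_genes, s_truth, s_reads = (int(s.generate_state(1)[0] % (2**31))
                                           for s in ss.spawn(4))
    pair = generate_genome_pair(config.n_contigs, config.contig_length,
                                config.divergence_rate,
                                config.n_rearranged_blocks, seed=s_genome)
    genes = generate_gene_models(pair, config.n_genes, seed=s_genes)
    truth = plant_apa_truth(
        genes, pair,
        pas_per_gene_distribution=config.pas_per_gene_distribution,
        location_probs=config.location_probs,
        divergent_fraction=config.divergent_fraction,
        min_true_dpau=config.min_true_dpau,
        max_true_dpau=config.max_true_dpau,
        species_specific_fraction=config.species_specific_fraction,
        motif_discordance=config.motif_discordance,
        dirichlet_alpha=config.dirichlet_alpha,
        seed=s_truth)
    read_sets = simulate_reads(pair, truth,
                               samples_per_species=config.samples_per_species,
                               reads_per_sample=config.reads_per_sample,
                               mispriming_rate=config.mispriming_rate,
                               jitter_max=config.jitter_max, seed=s_reads)
    return SimulatedDataset(config, pair, genes, truth, read_sets)


def write_dataset(dataset: SimulatedDataset, directory: str) -> Dict[str, object]:
    """Emit FASTA, GFF3, BED6 per sample, block map, truth TSVs + manifest."""
    os.makedirs(directory, exist_ok=True)
    files: Dict[str, str] = {}

    def path(name: str) -> str:
        files[name] = name
        return os.path.join(directory, name)

    akio.write_fasta(dataset.pair.sequences_a, path("genome_a.fa"))
    akio.write_fasta(dataset.pair.sequences_b, path("genome_b.fa"))
    write_gff3(dataset.genes, path("genes_a.gff3"))
    akio.write_block_map(dataset.pair.block_map_ab, path("blocks_ab.tsv"))
    dataset.truth.pas.to_csv(path("truth_pas.tsv"), sep="\t", index=False)
    dataset.truth.genes.to_csv(path("truth_genes.tsv"), sep="\t", index=False)
    for rs in dataset.read_sets:
        name = f"reads_{rs.sample_id}.bed"
        akio.write_reads_bed(rs.reads, path(name), rs.sample_id)
        rs.reads[["provenance"]].to_csv(
            path(f"provenance_{rs.sample_id}.tsv"), sep="\t", index=False)
    manifest = {
        "seed": dataset.config.seed,
        "config": asdict(dataset.config),
        "config_hash": dataset.config.config_hash(),
        "samples": [(rs.sample_id, rs.species, rs.fraction) for rs in dataset.read_sets],
        "files": files,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def simulate_dm_counts(n_null: int, n_planted: int = 0,
                       samples_per_species: Tuple[int, int] = (5, 6),
                       reads_per_sample: int = 200,
                       concentration: float = 50.0,
                       planted_dpau: float = 0.3,
                       pas_per_gene_distribution: Sequence[float] = DEFAULT_PAS_PER_GENE,
                       dirichlet_alpha: float = 0.9,
                       min_usage: float = 0.05,
                       seed: int = 0):
    """Count-level Dirichlet-multinomial simulation for test calibration.

    Per gene: K ≥ 2 PAS (the generator's PAS-count distribution truncated at
    2), a usage vector from Dirichlet(alpha) floored at ``min_usage`` (sites
    below the usage filter would not be tested), per-sample counts drawn
    multinomial with Dirichlet(concentration × usage) proportions.  Planted
    genes transfer ``planted_dpau`` usage mass between their most- and
    least-used PAS in species B (random sign).

    Returns (counts DataFrame pas × sample, pas2gene Series, species Series,
    truth DataFrame with per-PAS true dPAU and the per-gene planted flag).
    """
    rng = np.random.default_rng(seed)
    kdist = np.asarray(pas_per_gene_distribution[1:], dtype=float)
    kdist = kdist / kdist.sum()
    samples = [f"a{i+1}" for i in range(samples_per_species[0])] + \
              [f"b{i+1}" for i in range(samples_per_species[1])]
    species = pd.Series(["a"] * samples_per_species[0] + ["b"] * samples_per_species[1],
                        index=samples)
    rows, meta = [], []
    index = []
    for gi in range(n_null + n_planted):
        planted = gi >= n_null
        K = 2 + int(rng.choice(kdist.size, p=kdist))
        p = rng.dirichlet(np.full(K, dirichlet_alpha))
        p = np.maximum(p, min_usage)
        p = p / p.sum()
        pA, pB = p.copy(), p.copy()
        true_d = np.zeros(K)
        if planted:
            i, j = int(np.argmax(p)), int(np.argmin(p))
            if pA[i] < planted_dpau + 0.02:      # ensure the shift is feasible
                target = planted_dpau + 0.05
                scale = (1.0 - target) / (1.0 - pA[i])
                pA = pA * scale
                pA[i] = target
                pB = pA.copy()
                j = int(np.argmin(pA))
            pB[i] -= planted_dpau
            pB[j] += planted_dpau
            if rng.random() < 0.5:
                pA, pB = pB, pA
            true_d = pA - pB
        gene = f"sim{gi:05d}"
        X = np.empty((K, len(samples)), dtype=int)
        for si, s in enumerate(samples):
            pp = pA if species[s] == "a" else pB
            X[:, si] = rng.multinomial(reads_per_sample,
                                       rng.dirichlet(concentration * pp))
        for k in range(K):
            index.append(f"{gene}.p{k}")
            rows.append(X[k])
            meta.append(dict(pas_id=f"{gene}.p{k}", gene_id=gene,
                             true_dpau=true_d[k], planted=planted))
    counts = pd.DataFrame(rows, index=index, columns=samples)
    truth = pd.DataFrame(meta)
    pas2gene = truth.set_index("pas_id")["gene_id"]
    return counts, pas2gene, species, truth


def simulate_effect_tables(genes: pd.DataFrame, seed: int = 0,
                           base_rate: float = 0.10,
                           divergent_multiplier: float = 3.0,
                           coupling: float = 0.0,
                           location_signs: Optional[Dict[str, float]] = None,
                           noise_sd: float = 1.0,
                           source: str = "expression") -> pd.DataFrame:
    """Stand-in external effect table (expression / translation / protein).

    ``genes`` needs gene_id plus optional divergent_gene, top_dpau and
    top_location columns.  Significance flags are Bernoulli(base_rate),
    multiplied by ``divergent_multiplier`` for APA-divergent genes (capped at
    0.95); effect sizes are N(0, noise_sd) plus ``coupling`` × top_dpau with a
    per-location sign (default intron +1, utr3 −1).  Column contract matches
    :data:`apakit.enrichment.EFFECT_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    signs = {"intron": 1.0, "utr3": -1.0} if location_signs is None else location_signs
    n = len(genes)
    div = genes["divergent_gene"].to_numpy(dtype=bool) \
        if "divergent_gene" in genes.columns else np.zeros(n, dtype=bool)
    rate = np.where(div, min(0.95, base_rate * divergent_multiplier), base_rate)
    sig = rng.random(n) < rate
    effect = rng.normal(0.0, noise_sd, size=n)
    if coupling != 0.0 and "top_dpau" in genes.columns:
        dpau = genes["top_dpau"].fillna(0.0).to_numpy()
        loc = genes.get("top_location", pd.Series(["utr3"] * n)).to_numpy()
        sgn = np.array([signs.get(l, 0.0) for l in loc])
        effect = effect + coupling * sgn * dpau
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), "effect": effect,
                         "sig": sig, "source": source})


def read_dataset(directory: str) -> SimulatedDataset:
    """Round-trip loader for :func:`write_dataset` output."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("pas_per_gene_distribution", "location_probs",
                "samples_per_species"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimConfig(**cfg_dict)
    seq_a = akio.read_fasta(os.path.join(directory, "genome_a.fa"))
    seq_b = akio.read_fasta(os.path.join(directory, "genome_b.fa"))
    bm = akio.read_block_map(os.path.join(directory, "blocks_ab.tsv"))
    pair = GenomePair(seq_a, seq_b, bm)
    genes = read_gff3(os.path.join(directory, "genes_a.gff3"))
    pas = pd.read_csv(os.path.join(directory, "truth_pas.tsv"), sep="\t")
    gtab = pd.read_csv(os.path.join(directory, "truth_genes.tsv"), sep="\t")
    read_sets = []
    for sample_id, species, fraction in manifest["samples"]:
        rdf = akio.read_reads_bed(os.path.join(directory, f"reads_{sample_id}.bed"))
        prov = pd.read_csv(os.path.join(directory, f"provenance_{sample_id}.tsv"), sep="\t")
        rdf["provenance"] = prov["provenance"].to_numpy()
        rdf["sample"] = sample_id
        read_sets.append(ReadSet(sample_id, species, fraction, rdf))
    return SimulatedDataset(config, pair, genes, ApaTruth(pas, gtab), read_sets)
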