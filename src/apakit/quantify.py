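"""PAS annotation and usage quantification.

A catalog entry is assigned to a gene by testing its apex (in the annotation
species, species A) against feature categories in a fixed priority order —
3' UTR, then 5 kb downstream of the gene ("end"), then coding exons, then
5' UTR, then introns — strand-matched, first hit winning.  Reads are counted
into ±100 bp PAS regions strand-specifically; usage of a PAS in a sample is
its count over the total count of all PAS of the same gene, undefined (NaN,
not zero) when the gene received no reads in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pyranges as pr

from .genes import GeneModel

LOCATION_PRIORITY = ("utr3", "end", "cds", "utr5", "intron")


# ---------------------------------------------------------------------------
# genic assignment
# ---------------------------------------------------------------------------

def _category_frames(gene_models: Sequence[GeneModel], downstream_window: int,
                     contig_lengths: Dict[str, int] | None) -> Dict[str, pd.DataFrame]:
    frames: Dict[str, List[dict]] = {loc: [] for loc in LOCATION_PRIORITY}
    for g in gene_models:
        clen = None if contig_lengths is None else contig_lengths.get(g.contig)
        per = {
            "utr3": g.utr3,
            "end": [g.downstream_interval(downstream_window, clen)],
            "cds": g.cds,
            "utr5": g.utr5,
            "intron": g.introns,
        }
        for loc, ivals in per.items():
            for s, e in ivals:
                if e > s:
                    frames[loc].append(dict(Chromosome=g.contig, Start=s, End=e,
                                            Strand=g.strand, gene_id=g.gene_id,
                                            tx_end=g.tx_end()))
    return {loc: pd.DataFrame(rows) for loc, rows in frames.items()}


def assign_genic_location(catalog: pd.DataFrame, gene_models: Sequence[GeneModel],
                          downstream_window: int = 5000,
                          contig_lengths: Dict[str, int] | None = None) -> pd.DataFrame:
    """Assign each catalog entry to (gene, location) by the priority hierarchy.

    Entries without an apex in the annotation species, or whose apex overlaps
    no feature of any gene, are absent from the result (excluded downstream).
    Overlapping genes matching at the same priority resolve to the nearer
    transcript end; exact ties go to the lexicographically first gene_id.
    """
    cat = catalog.dropna(subset=["apex_a"])
    if len(cat) == 0:
        return pd.DataFrame(columns=["pas_id", "gene_id", "location"])
    points = pd.DataFrame({
        "Chromosome": cat["contig_a"],
        "Start": cat["apex_a"].astype(int),
        "End": cat["apex_a"].astype(int) + 1,
        "Strand": cat["strand_a"],
        "pas_id": cat["pas_id"],
        "apex": cat["apex_a"].astype(int),
    })
    frames = _category_frames(gene_models, downstream_window, contig_lengths)
    assigned: List[pd.DataFrame] = []
    remaining = points
    for loc in LOCATION_PRIORITY:
        feat = frames[loc]
        if len(remaining) == 0 or len(feat) == 0:
            continue
        j = pr.PyRanges(remaining).join(pr.PyRanges(feat), strandedness="same").df
        if len(j) == 0:
            continue
        j["dist_end"] = (j["apex"] - j["tx_end"]).abs()
        j = j.sort_values(["pas_id", "dist_end", "gene_id"])
        best = j.drop_duplicates("pas_id", keep="first")
        assigned.append(best.assign(location=loc)[["pas_id", "gene_id", "location"]])
        remaining = remaining[~remaining["pas_id"].isin(best["pas_id"])]
    if not assigned:
        return pd.DataFrame(columns=["pas_id", "gene_id", "location"])
    return pd.concat(assigned, ignore_index=True)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _trim_within_gene(df: pd.DataFrame, start_col: str, end_col: str,
                      apex_col: str) -> pd.DataFrame:
    """Trim overlapping regions of the same gene at the apex midpoint.

    Keeps within-gene regions disjoint so a read is counted to at most one
    PAS per gene; regions of different genes may still overlap.
    """
    df = df.copy()
    for _, idx in df.groupby(["gene_id", "contig", "strand"], sort=False).groups.items():
        sub = df.loc[idx].sort_values(apex_col)
        order = sub.index.to_list()
        for prev, cur in zip(order, order[1:]):
            if df.at[prev, end_col] > df.at[cur, start_col]:
                mid = int((df.at[prev, apex_col] + df.at[cur, apex_col]) // 2)
                df.at[prev, end_col] = mid
                df.at[cur, start_col] = mid
    return df


def count_reads(catalog: pd.DataFrame, reads: pd.DataFrame,
                assignments: pd.DataFrame) -> pd.DataFrame:
    """Count read 3'-ends into PAS regions, strand-aware, per sample.

    ``reads`` must carry contig / pos / strand / sample / species columns;
    species 'a' reads are matched against the species-A region coordinates and
    species 'b' reads against species B.  Returns a pas_id × sample count
    matrix (only assigned PAS appear).
    """
    cat = catalog.merge(assignments[["pas_id", "gene_id"]], on="pas_id", how="inner")
    samples = sorted(reads["sample"].unique())
    counts = pd.DataFrame(0, index=cat["pas_id"], columns=samples, dtype=int)
    for species in ("a", "b"):
        suffix = species
        sub = cat.dropna(subset=[f"apex_{suffix}"])
        if len(sub) == 0:
            continue
        regions = pd.DataFrame({
            "contig": sub[f"contig_{suffix}"],
            "strand": sub[f"strand_{suffix}"],
            "start": sub[f"start_{suffix}"].astype(int),
            "end": sub[f"end_{suffix}"].astype(int),
            "apex": sub[f"apex_{suffix}"].astype(int),
            "gene_id": sub["gene_id"],
            "pas_id": sub["pas_id"],
        })
        regions = _trim_within_gene(regions, "start", "end", "apex")
        rsub = reads[reads["species"] == species]
        if len(rsub) == 0:
            continue
        gr = pr.PyRanges(pd.DataFrame({
            "Chromosome": regions["contig"], "Start": regions["start"],
            "End": regions["end"], "Strand": regions["strand"],
            "pas_id": regions["pas_id"]}))
        rr = pr.PyRanges(pd.DataFrame({
            "Chromosome": rsub["contig"], "Start": rsub["pos"],
            "End": rsub["pos"] + 1, "Strand": rsub["strand"],
            "sample": rsub["sample"]}))
        j = gr.join(rr, strandedness="same").df
        if len(j) == 0:
            continue
        tab = j.groupby(["pas_id", "sample"]).size().unstack(fill_value=0)
        counts = counts.add(tab.reindex(index=counts.index, columns=samples,
                                        fill_value=0), fill_value=0).astype(int)
    return counts


# ---------------------------------------------------------------------------
# usage and filters
# ---------------------------------------------------------------------------

def usage_fractions(counts: pd.DataFrame, pas2gene: pd.Series) -> pd.DataFrame:
    """Per-sample usage = PAS count / gene total; NaN where the total is 0."""
    genes = pas2gene.reindex(counts.index)
    gene_totals = counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = counts / gene_totals
    return usage.where(gene_totals > 0)


@dataclass
class FilteredQuant:
    """Counts and recomputed usage over the PAS surviving both filters."""

    counts: pd.DataFrame
    usage: pd.DataFrame
    pas2gene: pd.Series
    dropped_low_usage: pd.Index
    dropped_low_expression: pd.Index


def mean_usage_by_species(usage: pd.DataFrame, species_of_sample: pd.Series) -> pd.DataFrame:
    """Per-PAS mean usage per species, ignoring samples with undefined usage."""
    out = {}
    for sp in sorted(species_of_sample.unique()):
        cols = species_of_sample.index[species_of_sample == sp]
        out[sp] = usage[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def apply_filters(counts: pd.DataFrame, pas2gene: pd.Series,
                  species_of_sample: pd.Series, min_usage: float = 0.05,
                  cpm_threshold: float = 2.0, cpm_min_samples: int = 8,
                  pseudo_count: float = 0.5) -> FilteredQuant:
    """Usage filter, then gene-expression (CPM) filter, then recompute usage.

    A PAS is dropped when its mean usage is below ``min_usage`` in *both*
    species (kept if at least one species reaches the cutoff).  Genes must
    reach log2 CPM above ``cpm_threshold`` in at least ``cpm_min_samples``
    samples, with CPM computed from the gene's summed PAS counts against the
    sample's total PAS-assigned reads (pseudo-count added before scaling);
    all PAS of failing genes are dropped.  Usage is recomputed over survivors.
    """
    n_samples = len(species_of_sample)
    if cpm_min_samples > n_samples:
        raise ValueError(f"cpm_min_samples={cpm_min_samples} exceeds "
                         f"sample count {n_samples}")
    pas2gene = pas2gene.reindex(counts.index)

    usage0 = usage_fractions(counts, pas2gene)
    mean_sp = mean_usage_by_species(usage0, species_of_sample)
    low = (mean_sp.fillna(0) < min_usage).all(axis=1)
    dropped_usage = counts.index[low]
    counts1 = counts.loc[~low]
    genes1 = pas2gene.loc[counts1.index]

    gene_counts = counts1.groupby(genes1).sum()
    lib = counts1.sum(axis=0)
    log_cpm = np.log2((gene_counts + pseudo_count).div(lib, axis=1) * 1e6)
    ok_genes = (log_cpm > cpm_threshold).sum(axis=1) >= cpm_min_samples
    keep_genes = set(ok_genes.index[ok_genes])
    keep = genes1.isin(keep_genes)
    dropped_expr = counts1.index[~keep]
    counts2 = counts1.loc[keep]
    genes2 = genes1.loc[counts2.index]

    usage2 = usage_fractions(counts2, genes2)
    return FilteredQuant(counts=counts2, usage=usage2, pas2gene=genes2,
                         dropped_low_usage=dropped_usage,
                         dropped_low_expression=dropped_expr)


def classify_species_specific(usage: pd.DataFrame, species_of_sample: pd.Series,
                              min_usage: float = 0.05) -> pd.Series:
    """Label PAS a_specific / b_specific / shared.

    A PAS is species-specific when its mean usage reaches ``min_usage`` in one
    species and is exactly zero in the other (both means taken over samples
    where usage is defined; a species with no defined sample cannot certify a
    zero, so such PAS stay shared).
    """
    mean_sp = mean_usage_by_species(usage, species_of_sample)
    a, b = mean_sp.get("a"), mean_sp.get("b")
    labels = pd.Series("shared", index=usage.index, name="species_specific")
    if a is None or b is None:
        return labels
    labels[(a >= min_usage) & (b == 0.0)] = "a_specific"
    labels[(b >= min_usage) & (a == 0.0)] = "b_specific"
    return labels
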