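"""End-to-end driver: reads → filter → peaks → catalog → usage → statistics.

Glues the stage modules together in the order the analysis defines and keeps
their intermediate products for inspection.  Also provides the truth-matching
helpers the synthetic benchmarks use (apex recovery, filter audit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import differential, diversity, mispriming, peaks, quantify
from .simulate import SimulatedDataset


@dataclass
class PipelineResult:
    catalog: pd.DataFrame
    assignments: pd.DataFrame
    counts: pd.DataFrame
    quant: quantify.FilteredQuant
    species_of_sample: pd.Series
    species_specific: pd.Series
    diff: differential.DifferentialResult
    diversity_tests: pd.DataFrame
    dominance_a: pd.DataFrame
    dominance_b: pd.DataFrame
    sharing: pd.DataFrame
    filter_stats: Dict[str, mispriming.FilterStats]
    kept_reads: pd.DataFrame


def run_pipeline(dataset: SimulatedDataset,
                 min_reads: int = 5, merge_distance: int = 30,
                 min_usage: float = 0.05, cpm_threshold: float = 2.0,
                 cpm_min_samples: Optional[int] = None,
                 fdr: float = 0.05, dpau_min: float = 0.2,
                 method: str = "dirichlet_multinomial") -> PipelineResult:
    """Run the full comparative APA analysis on a simulated dataset.

    ``cpm_min_samples`` defaults to 8 (the study's 8-of-12 rule) capped at the
    actual sample count for small designs.
    """
    reads = dataset.reads_frame()
    species_of_sample = pd.Series(
        {rs.sample_id: rs.species for rs in dataset.read_sets})
    n_samples = len(species_of_sample)
    if cpm_min_samples is None:
        cpm_min_samples = min(8, n_samples)

    # 1. mispriming filter, per species against its own genome
    kept_parts, stats = [], {}
    for sp in ("a", "b"):
        sub = reads[reads["species"] == sp]
        kept, st = mispriming.filter_reads(sub, dataset.pair.sequences(sp))
        kept_parts.append(kept)
        stats[sp] = st
    kept_reads = pd.concat(kept_parts, ignore_index=True)

    # 2. peak calling per species (samples pooled), then the unified catalog
    peaks_a = peaks.call_peaks(kept_reads[kept_reads["species"] == "a"],
                               min_reads=min_reads, merge_distance=merge_distance)
    peaks_b = peaks.call_peaks(kept_reads[kept_reads["species"] == "b"],
                               min_reads=min_reads, merge_distance=merge_distance)
    catalog = peaks.unify_pas(peaks_a, peaks_b, dataset.pair)

    # 3. genic annotation (species A) and counting
    contig_lengths = {c: len(s) for c, s in dataset.pair.sequences_a.items()}
    assignments = quantify.assign_genic_location(catalog, dataset.genes,
                                                 contig_lengths=contig_lengths)
    counts = quantify.count_reads(catalog, kept_reads, assignments)

    # 4. usage + filters + species-specific labels
    pas2gene = assignments.set_index("pas_id")["gene_id"]
    quant = quantify.apply_filters(counts, pas2gene, species_of_sample,
                                   min_usage=min_usage,
                                   cpm_threshold=cpm_threshold,
                                   cpm_min_samples=cpm_min_samples)
    sspec = quantify.classify_species_specific(quant.usage, species_of_sample,
                                               min_usage=min_usage)

    # 5. differential usage
    diff = differential.fit_differential(quant.counts, quant.pas2gene,
                                         species_of_sample, method=method)
    diff = differential.classify_divergent(diff, fdr=fdr, dpau_min=dpau_min)

    # 6. diversity + dominance
    d_by_sample = diversity.per_sample_simpson(quant.usage, quant.pas2gene)
    n_pas = quant.pas2gene.value_counts()
    div_tests = diversity.diversity_difference_test(d_by_sample, species_of_sample,
                                                    min_pas=n_pas)
    mean_sp = quantify.mean_usage_by_species(quant.usage, species_of_sample)
    ptab = catalog.set_index("pas_id").loc[quant.usage.index]
    base = pd.DataFrame({
        "pas_id": quant.usage.index,
        "gene_id": quant.pas2gene.to_numpy(),
        "apex": ptab["apex_a"].to_numpy(),
        "strand": ptab["strand_a"].to_numpy(),
    })
    dom_a = diversity.dominance_records(base.assign(mean_usage=mean_sp["a"].to_numpy()))
    dom_b = diversity.dominance_records(base.assign(mean_usage=mean_sp["b"].to_numpy()))
    sharing = diversity.sharing_by_cutoff(dom_a, dom_b)

    return PipelineResult(catalog=catalog, assignments=assignments, counts=counts,
                          quant=quant, species_of_sample=species_of_sample,
                          species_specific=sspec, diff=diff,
                          diversity_tests=div_tests, dominance_a=dom_a,
                          dominance_b=dom_b, sharing=sharing,
                          filter_stats=stats, kept_reads=kept_reads)


# ---------------------------------------------------------------------------
# truth matching
# ---------------------------------------------------------------------------

def match_catalog_to_truth(catalog: pd.DataFrame, truth_pas: pd.DataFrame,
                           tolerance: int = 5) -> pd.DataFrame:
    """Pair planted PAS with the nearest catalog apex on the same strand.

    Returns the truth table with matched pas_id and the apex error
    (catalog − planted, NaN when no entry lies within ``tolerance`` bp).
    """
    cat = catalog.dropna(subset=["apex_a"])
    out_ids, out_err = [], []
    by_key = {k: sub.sort_values("apex_a")
              for k, sub in cat.groupby(["contig_a", "strand_a"])}
    for r in truth_pas.itertuples(index=False):
        sub = by_key.get((r.contig, r.strand))
        if sub is None or len(sub) == 0:
            out_ids.append(None)
            out_err.append(np.nan)
            continue
        apexes = sub["apex_a"].to_numpy()
        j = int(np.argmin(np.abs(apexes - r.apex_a)))
        err = apexes[j] - r.apex_a
        if abs(err) <= tolerance:
            out_ids.append(sub["pas_id"].iloc[j])
            out_err.append(int(err))
        else:
            out_ids.append(None)
            out_err.append(np.nan)
    out = truth_pas.copy()
    out["matched_pas_id"] = out_ids
    out["apex_error"] = out_err
    return out


def true_read_support(reads: pd.DataFrame) -> pd.Series:
    """Reads per planted PAS (provenance counts, misprimed excluded)."""
    per_pas = reads[reads["provenance"] != "misprimed"]
    return per_pas.groupby("provenance").size()
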