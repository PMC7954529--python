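"""Enrichment and correlation analyses joining APA results with external data.

Overlap enrichment is reported as fold = (k/n)/(K/N) with an exact one-sided
upper-tail hypergeometric probability P(X ≥ k) (the observed count included),
always together with the (k, n, K, N) quadruple so every number can be
recomputed.  Effect-size integration (differential expression, translation,
protein, ubiquitination) consumes external tables with a declared column
contract: gene_id, effect, sig (boolean at the source's FDR), source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, spearmanr

from .diversity import CUTOFF_GRID, SAME_DOMINANT, DIFFERENT_DOMINANT

EFFECT_COLUMNS = ("gene_id", "effect", "sig", "source")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap k of n draws against K of N; fold and upper-tail p."""

    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Exact one-sided overlap enrichment.

    ``k`` foreground genes of ``n`` drawn carry an annotation held by ``K`` of
    the ``N`` background genes.  fold = (k/n)/(K/N); p = P(X ≥ k) under the
    hypergeometric null.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if not (k <= n <= N and K <= N and k <= K):
        raise ValueError(f"inconsistent quadruple k={k} n={n} K={K} N={N}")
    if n == 0 or K == 0:
        raise ValueError("n and K must be positive for a fold to exist")
    fold = (k / n) / (K / N)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=int(k), n=int(n), K=int(K), N=int(N),
                            fold=fold, p=min(1.0, p))


def enrichment_from_sets(foreground: Iterable, annotated: Iterable,
                         background: Iterable) -> EnrichmentResult:
    """Convenience wrapper computing the quadruple from gene sets."""
    bg = set(background)
    fg = set(foreground) & bg
    ann = set(annotated) & bg
    return hypergeom_enrichment(len(fg & ann), len(fg), len(ann), len(bg))


# ---------------------------------------------------------------------------
# effect-size correlation
# ---------------------------------------------------------------------------

def correlate_effects(dpau_table: pd.DataFrame, effect_table: pd.DataFrame,
                      by_location: bool = True,
                      significant_only: bool = False,
                      apa_sig: Optional[pd.Series] = None) -> pd.DataFrame:
    """Pearson + Spearman between per-gene dPAU and an external effect size.

    ``dpau_table`` is the one-PAS-per-gene(-per-location) selection from
    ``top_pas_per_gene`` (gene_id, dpau, location); the join is inner on
    gene_id.  With ``significant_only`` the pairs are restricted to genes
    significant in both phenotypes (``sig`` flag in the effect table,
    ``apa_sig`` boolean series over gene_id).  Subsets with <3 genes are
    reported with NaN coefficients and a reason.
    """
    joined = dpau_table.merge(effect_table, on="gene_id", how="inner")
    if significant_only:
        if apa_sig is None:
            raise ValueError("significant_only requires apa_sig flags")
        joined = joined[joined["sig"]
                        & apa_sig.reindex(joined["gene_id"]).fillna(False).to_numpy()]
    subsets: List[Tuple[str, pd.DataFrame]] = [("all", joined)]
    if by_location:
        subsets += [(loc, joined[joined["location"] == loc])
                    for loc in sorted(joined["location"].dropna().unique())]
    rows = []
    for name, sub in subsets:
        sub = sub.dropna(subset=["dpau", "effect"])
        if len(sub) < 3:
            rows.append(dict(subset=name, n=len(sub), pearson_r=np.nan,
                             pearson_p=np.nan, spearman_r=np.nan,
                             spearman_p=np.nan, reason="fewer than 3 genes"))
            continue
        pr_ = pearsonr(sub["dpau"], sub["effect"])
        sr = spearmanr(sub["dpau"], sub["effect"])
        rows.append(dict(subset=name, n=len(sub),
                         pearson_r=float(pr_.statistic), pearson_p=float(pr_.pvalue),
                         spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue),
                         reason=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein-not-mRNA decomposition
# ---------------------------------------------------------------------------

def protein_not_mrna(expression_table: pd.DataFrame, protein_table: pd.DataFrame,
                     apa_classes: pd.Series
                     ) -> Tuple[pd.DataFrame, Optional[EnrichmentResult]]:
    """Genes divergent in protein but not mRNA, split by APA divergence class.

    ``apa_classes`` maps gene_id to one of {"pas_only", "diversity_only",
    "both", "none"} (APA divergence at the site level, the isoform-diversity
    level, both, or neither).  The background is the intersection of genes
    tested in both external phenotypes and in APA.  Returns the per-class
    counts of protein-significant/mRNA-nonsignificant genes plus the
    enrichment of APA-divergent genes (any class but "none") in that set.
    """
    expr = expression_table.set_index("gene_id")
    prot = protein_table.set_index("gene_id")
    background = expr.index.intersection(prot.index).intersection(apa_classes.index)
    psig = prot.loc[background, "sig"].astype(bool)
    esig = expr.loc[background, "sig"].astype(bool)
    target = background[psig & ~esig]
    classes = apa_classes.loc[background]
    counts = classes.loc[target].value_counts()
    table = pd.DataFrame({
        "apa_class": counts.index,
        "n_protein_not_mrna": counts.to_numpy(),
    })
    apa_div = set(background[classes != "none"])
    if len(target) == 0 or len(apa_div) == 0:
        return table, None    # no foreground or annotation: fold undefined
    enr = enrichment_from_sets(target, apa_div, background)
    return table, enr


def dominance_de_enrichment(sharing: pd.DataFrame, de_flags: pd.Series,
                            cutoffs: Iterable[float] = CUTOFF_GRID) -> pd.DataFrame:
    """DE enrichment of same-/different-dominant genes per cutoff.

    ``sharing`` is the long per-gene table from ``sharing_by_cutoff``;
    ``de_flags`` a boolean series over gene_id (differentially expressed).
    Background per cutoff = genes present in both analyses.  Empty classes
    are reported with NaN and a reason.
    """
    rows = []
    de_flags = de_flags.astype(bool)
    for c in cutoffs:
        sub = sharing[np.isclose(sharing["cutoff"], c)]
        bg = pd.Index(sub["gene_id"]).intersection(de_flags.index)
        de_genes = set(de_flags.index[de_flags])
        for cls in (SAME_DOMINANT, DIFFERENT_DOMINANT):
            fg = pd.Index(sub.loc[sub["sharing"] == cls, "gene_id"]).intersection(bg)
            if len(fg) == 0 or len(bg) == 0 or len(de_genes & set(bg)) == 0:
                rows.append(dict(cutoff=c, sharing=cls, k=0, n=len(fg),
                                 K=len(de_genes & set(bg)), N=len(bg),
                                 fold=np.nan, p=np.nan, reason="empty class"))
                continue
            e = enrichment_from_sets(fg, de_genes, bg)
            rows.append(dict(cutoff=c, sharing=cls, k=e.k, n=e.n, K=e.K, N=e.N,
                             fold=e.fold, p=e.p, reason=""))
    return pd.DataFrame(rows)


def normalize_ubiquitination(site_counts: pd.Series,
                             protein_lengths: pd.Series) -> pd.Series:
    """Ubiquitination sites per amino acid; genes without a length are NaN."""
    lengths = protein_lengths.reindex(site_counts.index)
    if (lengths.dropna() <= 0).any():
        raise ValueError("protein lengths must be positive")
    return site_counts / lengths
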