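"""Differential PAS usage between species.

Each multi-PAS gene is tested with a two-group Dirichlet-multinomial (DM)
likelihood-ratio test: per-sample PAS counts are DM distributed with a usage
(proportion) vector and a concentration shared between groups; the null fits
one usage vector for all samples, the alternative one per species, and twice
the log-likelihood gap is referred to chi-square with (#PAS − 1) degrees of
freedom.  The DM's concentration absorbs the biological overdispersion that a
plain multinomial (also available as ``method="multinomial"``) would mistake
for signal.

Effect sizes are reported per PAS as dPAU = mean usage in species A minus
mean usage in species B (per-sample usage fractions averaged within species),
so a negative dPAU means higher usage in the B (chimpanzee-analog) species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, digamma
from scipy.stats import chi2

STATUS_TESTED = "tested"
STATUS_NOT_TESTED = "not_tested"
STATUS_FAILED = "fit_failed"

_LOG_ALPHA_BOUNDS = (np.log(1e-3), np.log(1e7))
_LOGIT_BOUND = 30.0


def _softmax_last_zero(t: np.ndarray) -> np.ndarray:
    z = np.concatenate([t, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _group_ll_grad(X: np.ndarray, n: np.ndarray, p: np.ndarray, a: float):
    """DM log-likelihood of one group plus pieces of its gradient.

    Returns (ll, g, da) with g_k = sum_s psi(x_sk + a p_k) - psi(a p_k) and
    da = sum_s (psi(a) - psi(n_s + a)) + sum_k p_k g_k, so that
    dll/dlog a = a * da and dll/dp_k = a * g_k.
    """
    ap = a * p
    ll = (gammaln(a) - gammaln(n + a)).sum() \
        + (gammaln(X + ap) - gammaln(ap)).sum()
    g = (digamma(X + ap) - digamma(ap)).sum(axis=0)
    da = (digamma(a) - digamma(n + a)).sum() + (p * g).sum()
    return ll, g, da


def _neg_ll_null(params: np.ndarray, X: np.ndarray, n: np.ndarray):
    K = X.shape[1]
    t, lam = params[:K - 1], params[-1]
    p = _softmax_last_zero(t)
    a = np.exp(lam)
    ll, g, da = _group_ll_grad(X, n, p, a)
    gbar = (p * g).sum()
    grad_t = a * p[:-1] * (g[:-1] - gbar)
    grad = np.concatenate([grad_t, [a * da]])
    return -ll, -grad


def _neg_ll_alt(params: np.ndarray, XA: np.ndarray, nA: np.ndarray,
                XB: np.ndarray, nB: np.ndarray):
    K = XA.shape[1]
    tA, tB, lam = params[:K - 1], params[K - 1:2 * (K - 1)], params[-1]
    pA, pB = _softmax_last_zero(tA), _softmax_last_zero(tB)
    a = np.exp(lam)
    llA, gA, daA = _group_ll_grad(XA, nA, pA, a)
    llB, gB, daB = _group_ll_grad(XB, nB, pB, a)
    gradA = a * pA[:-1] * (gA[:-1] - (pA * gA).sum())
    gradB = a * pB[:-1] * (gB[:-1] - (pB * gB).sum())
    grad = np.concatenate([gradA, gradB, [a * (daA + daB)]])
    return -(llA + llB), -grad


def _empirical_logits(X: np.ndarray) -> np.ndarray:
    p = X.sum(axis=0) + 0.5
    p = p / p.sum()
    return np.log(p[:-1] / p[-1])


def _optimize(fun, x0_list: Iterable[np.ndarray], args, n_logits: int):
    """Best of several deterministic starts; None if nothing converges."""
    best = None
    bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * n_logits + [_LOG_ALPHA_BOUNDS]
    for x0 in x0_list:
        res = optimize.minimize(fun, x0, args=args, jac=True, method="L-BFGS-B",
                                bounds=bounds)
        if res.success or np.max(np.abs(res.jac)) < 1e-3:
            if best is None or res.fun < best.fun:
                best = res
    return best


def dm_lrt(XA: np.ndarray, XB: np.ndarray) -> Tuple[float, float, int]:
    """Two-group DM likelihood-ratio test on sample × PAS count matrices.

    Returns (LRT statistic, p-value, df); p is NaN if the fit fails at all
    three deterministic starts.
    """
    XA = np.asarray(XA, dtype=float)
    XB = np.asarray(XB, dtype=float)
    K = XA.shape[1]
    nA, nB = XA.sum(axis=1), XB.sum(axis=1)
    X0 = np.vstack([XA, XB])
    n0 = np.concatenate([nA, nB])
    t0 = _empirical_logits(X0)
    starts0 = [np.concatenate([t0, [np.log(a0)]]) for a0 in (10.0, 1.0, 100.0)]
    null = _optimize(_neg_ll_null, starts0, (X0, n0), K - 1)
    tA0, tB0 = _empirical_logits(XA), _empirical_logits(XB)
    starts1 = [np.concatenate([tA0, tB0, [np.log(a0)]]) for a0 in (10.0, 1.0, 100.0)]
    alt = _optimize(_neg_ll_alt, starts1, (XA, nA, XB, nB), 2 * (K - 1))
    df = K - 1
    if null is None or alt is None:
        return np.nan, np.nan, df
    lrt = max(0.0, 2.0 * (null.fun - alt.fun))
    return lrt, float(chi2.sf(lrt, df)), df


def multinomial_lrt(XA: np.ndarray, XB: np.ndarray) -> Tuple[float, float, int]:
    """Plain multinomial two-group LRT (no overdispersion), closed form."""
    XA = np.asarray(XA, dtype=float)
    XB = np.asarray(XB, dtype=float)
    K = XA.shape[1]

    def ll(X: np.ndarray) -> float:
        col = X.sum(axis=0)
        tot = col.sum()
        if tot == 0:
            return 0.0
        p = col / tot
        mask = col > 0
        return float((col[mask] * np.log(p[mask])).sum())

    lrt = max(0.0, 2.0 * (ll(XA) + ll(XB) - ll(np.vstack([XA, XB]))))
    df = K - 1
    return lrt, float(chi2.sf(lrt, df)), df


# ---------------------------------------------------------------------------
# per-gene driver
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Gene-level tests plus per-PAS effect sizes.

    ``genes``: gene_id, lrt, df, p, q, status.  ``pas``: pas_id, gene_id,
    dpau, mean_usage (grand mean of per-sample usage over all samples).
    """

    genes: pd.DataFrame
    pas: pd.DataFrame


def fit_differential(counts: pd.DataFrame, pas2gene: pd.Series,
                     species_of_sample: pd.Series,
                     method: str = "dirichlet_multinomial",
                     min_samples_per_species: int = 2) -> DifferentialResult:
    """Test every eligible gene for differential PAS usage between species.

    A gene is tested when it has ≥2 PAS and at least ``min_samples_per_species``
    samples with nonzero totals in each species; others are reported with
    status ``not_tested`` and NaN p.  dPAU is computed for every gene with ≥1
    usable sample per species regardless of test status.
    """
    if method not in ("dirichlet_multinomial", "multinomial"):
        raise ValueError(f"unknown method {method!r}")
    test = dm_lrt if method == "dirichlet_multinomial" else multinomial_lrt
    samples_a = [s for s in counts.columns if species_of_sample[s] == "a"]
    samples_b = [s for s in counts.columns if species_of_sample[s] == "b"]
    gene_rows: List[dict] = []
    pas_rows: List[dict] = []
    pas2gene = pas2gene.reindex(counts.index)
    for gene, idx in counts.groupby(pas2gene).groups.items():
        sub = counts.loc[idx]
        XA = sub[samples_a].to_numpy().T   # samples × PAS
        XB = sub[samples_b].to_numpy().T
        totA, totB = XA.sum(axis=1), XB.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            uA = np.where(totA[:, None] > 0, XA / totA[:, None], np.nan)
            uB = np.where(totB[:, None] > 0, XB / totB[:, None], np.nan)
        okA, okB = (totA > 0).sum(), (totB > 0).sum()
        mA = np.nanmean(uA, axis=0) if okA else np.full(len(sub), np.nan)
        mB = np.nanmean(uB, axis=0) if okB else np.full(len(sub), np.nan)
        dpau = mA - mB
        allu = np.vstack([uA, uB])
        grand = np.nanmean(allu, axis=0) if (okA or okB) else np.full(len(sub), np.nan)
        eligible = (len(sub) >= 2 and okA >= min_samples_per_species
                    and okB >= min_samples_per_species)
        if eligible:
            lrt, p, df = test(XA[totA > 0], XB[totB > 0])
            status = STATUS_TESTED if np.isfinite(p) else STATUS_FAILED
        else:
            lrt, p, df = np.nan, np.nan, len(sub) - 1
            status = STATUS_NOT_TESTED
        gene_rows.append(dict(gene_id=gene, lrt=lrt, df=df, p=p, status=status))
        for pid, d, g in zip(sub.index, dpau, grand):
            pas_rows.append(dict(pas_id=pid, gene_id=gene, dpau=d, mean_usage=g))
    genes = pd.DataFrame(gene_rows)
    genes["q"] = bh_fdr(genes["p"].to_numpy())
    return DifferentialResult(genes=genes, pas=pd.DataFrame(pas_rows))


# ---------------------------------------------------------------------------
# FDR and classification
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN inputs propagate."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[finite] = qv
    return q


def classify_divergent(result: DifferentialResult, fdr: float = 0.05,
                       dpau_min: float = 0.2) -> DifferentialResult:
    """Flag divergent PAS (gene q < fdr and |dPAU| strictly above dpau_min).

    Adds a ``divergent`` column to the PAS table and a ``gene_class`` column
    (divergent / conserved / not_tested) to the gene table.
    """
    genes = result.genes.copy()
    pas = result.pas.copy()
    qmap = genes.set_index("gene_id")["q"]
    smap = genes.set_index("gene_id")["status"]
    gene_q = qmap.reindex(pas["gene_id"]).to_numpy()
    pas["divergent"] = (gene_q < fdr) & (pas["dpau"].abs() > dpau_min)
    pas.loc[smap.reindex(pas["gene_id"]).to_numpy() != STATUS_TESTED,
            "divergent"] = False
    div_genes = set(pas.loc[pas["divergent"], "gene_id"])
    cls = np.where(genes["status"] != STATUS_TESTED, STATUS_NOT_TESTED,
                   np.where(genes["gene_id"].isin(div_genes), "divergent",
                            "conserved"))
    genes["gene_class"] = cls
    return DifferentialResult(genes=genes, pas=pas)


def top_pas_per_gene(pas: pd.DataFrame,
                     locations: Tuple[str, ...] = ("utr3", "intron")) -> pd.DataFrame:
    """One PAS per gene per genic-location class: the largest |dPAU|.

    The gene-level p is shared by all its PAS, so within a gene significance
    ranks by |dPAU|; ties break toward the larger grand-mean usage.  Requires
    a ``location`` column (join with the genic assignment first).
    """
    sub = pas[pas["location"].isin(locations)].copy()
    sub["absd"] = sub["dpau"].abs()
    sub = sub.sort_values(["gene_id", "location", "absd", "mean_usage"],
                          ascending=[True, True, False, False])
    out = sub.drop_duplicates(["gene_id", "location"], keep="first")
    return out.drop(columns="absd").reset_index(drop=True)
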