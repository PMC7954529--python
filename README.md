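# apakit

Comparative analysis of alternative polyadenylation (APA) between two closely
related species from 3'-end sequencing (3' Seq) data.

Most genes carry more than one polyadenylation site (PAS); which site is used
determines the 3' UTR length and, for intronic sites, the coding sequence of
the mRNA isoform.  `apakit` implements the full analysis chain needed to ask
how PAS usage diverges between two species — e.g. a human/chimpanzee
lymphoblastoid-cell comparison — from mapped read 3'-end positions to
statistics:

* **Internal-priming filter** — 3' Seq relies on an oligo-dT primer that can
  also bind genomic adenine stretches.  A read is discarded when the 10
  genomic bases past its 3' end contain `AAAAAA` or ≥7 adenines (ambiguous
  `N` bases count as A).
* **PAS discovery** — strand-aware clustering of read ends into peaks; the
  PAS apex is the most 3' covered base of a peak.  Apexes are extended
  ±100 bp into comparison regions and projected through a reciprocal
  block-map (liftover stand-in) to build one cross-species catalog.
* **Usage quantification** — usage of PAS *i* in sample *s* is
  `u_is = x_is / Σ_j x_js` over the PAS of the same gene; sites under 5% mean
  usage in both species and genes under log2 CPM 2 in most samples are
  filtered; sites used ≥5% in one species and exactly 0% in the other are
  called species-specific.
* **Differential usage** — per multi-PAS gene, a two-group
  Dirichlet-multinomial likelihood-ratio test (species-specific usage vectors
  vs a shared one, shared concentration; chi-square with #PAS−1 df), BH FDR
  across genes, and per-site effect sizes ΔPAU = mean usage(species A) −
  mean usage(species B).  A PAS is divergent when its gene passes 5% FDR and
  |ΔPAU| > 0.2.
* **Isoform diversity and dominance** — Simpson's D = 1 − Σp² and Shannon
  H = −Σp log2 p per gene; per-gene exact Wilcoxon rank-sum on per-individual
  D between species; dominance = usage gap between a gene's top two sites,
  with cross-species sharing classified over a 0.1–0.9 cutoff grid.
* **Sequence features** — the 12 polyadenylation signal hexamers scanned in
  fixed priority order (AATAAA first), species-specific signal calls
  restricted to the two usage-promoting motifs, U content, AU-rich-element
  coverage of 3' UTRs, and mean conservation scores over the PAS region and
  three 200 bp windows on each side.
* **Integration** — exact one-sided hypergeometric enrichments (always
  reported with their (k, n, K, N) quadruple), ΔPAU / effect-size
  correlations split by genic location, and the decomposition of
  protein-but-not-mRNA expression differences by APA divergence class.

Everything is developed and tested against a first-class synthetic-data
module (`apakit.simulate`) that generates two block-rearranged genomes, gene
models, planted PAS with known usage vectors and signal motifs, and 3'-Seq
reads including filter-recoverable internal-priming artifacts.

## Worked example

```python
from apakit import SimConfig, simulate_dataset, run_pipeline

cfg = SimConfig(n_genes=15, reads_per_sample=20_000,
                samples_per_species=(3, 3), seed=7)
ds = simulate_dataset(cfg)          # genomes, genes, truth, reads
res = run_pipeline(ds, cpm_min_samples=4)

print("planted PAS:", len(ds.truth.pas))
print("catalog entries:", len(res.catalog),
      "| shared origin:", (res.catalog["origin"] == "both").sum())
print("PAS surviving filters:", len(res.quant.counts))
print(res.diff.genes["gene_class"].value_counts().to_dict())
```

prints

```
planted PAS: 48
catalog entries: 48 | shared origin: 48
PAS surviving filters: 41
{'conserved': 9, 'not_tested': 5, 'divergent': 1}
```

All 48 planted sites are recovered and identified in both species; 7 sites
fall below the 5%-usage filter; single-PAS genes are not tested, and one gene
with a planted usage shift is called divergent.  Enrichment statistics come
with full provenance:

```python
from apakit.enrichment import hypergeom_enrichment
e = hypergeom_enrichment(14, 302, 361, 44432)
print(f"fold={e.fold:.2f}  p={e.p:.2e}")   # fold=5.71  p=2.30e-07
```

A thin CLI mirrors the pipeline stages:

```bash
apa simulate --config cfg.yaml --out data/ --seed 3
apa filter  --reads data/reads_a1.bed --genome data/genome_a.fa --out kept.bed
apa callpas --reads kept.bed --out peaks.tsv
apa diff    --counts counts.tsv --groups groups.tsv --out diff.tsv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the full synthetic world from the seed (500 genes, 5 + 6 samples,
~200 reads/gene/sample, 2% internal-priming artifacts), runs the entire
pipeline — filtering, peak calling, reciprocal cataloging, quantification,
differential usage, diversity and dominance — and prints a run summary
(apex-recovery rate, artifact removal, gene classifications) before writing
the JSON report.

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
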