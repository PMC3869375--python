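# enact

Enhancer-centric analysis of ChIP-seq and RNA-seq tag libraries: island
peak calling with a knockout-based specificity filter, chromatin-state
classification of regulatory elements, TF co-localization statistics,
expression-dependence calls, and enhancer-to-gene assignment — with a
seeded synthetic-data generator that carries ground truth for every stage.

## The problem

During cell differentiation, lineage-determining transcription factors
(in adipogenesis: C/EBPα, C/EBPβ and PPARγ; in myogenesis: MyoD) act
through *enhancers* — distal regulatory elements marked by H3K4me1/2 and,
when active, by H3K27ac.  The H3K4 mono-/di-methyltransferase MLL4
(KMT2D) marks these enhancers, and its loss collapses both the enhancer
chromatin state and the induction of cell-type-specific genes.  Testing
that model computationally requires a chain of analyses:

1. **Island calling.**  ChIP-enriched regions are found by tiling the
   genome into windows of width *W* (200 bp for broad histone marks,
   50 bp for point-source factors), marking windows whose tag count is
   improbable under a uniform Poisson background
   (P(X ≥ c; λ) < 0.2, λ = *NW*/*L*<sub>eff</sub>), and stitching
   eligible windows separated by at most one gap window into islands.
   Each island is tested against a control library with a one-sided
   Poisson test and filtered by Benjamini–Hochberg FDR (10⁻³ for histone
   marks, 10⁻¹⁵ for factors against input, 10⁻⁵ for low-coverage
   samples).
2. **Specificity filter.**  Antibody artifacts are removed by keeping
   only islands whose enrichment in control cells significantly exceeds
   the depth-scaled signal in knockout cells (FDR < 10⁻¹⁵).
3. **Chromatin states.**  Four mutually exclusive element classes:
   active/silent promoters (H3K4me3 ± H3K27ac at a TSS) and active/silent
   enhancers (distal H3K4me1 ± H3K27ac).
4. **Co-localization statistics.**  1-bp overlap defines co-localization;
   enrichment is tested with hypergeometric and binomial upper tails
   computed in log space (the p-values involved go far below the double
   underflow limit, e.g. p < 10⁻³⁰⁰).
5. **Expression dependence.**  RPKM per gene over the exon union; genes
   with over 2.5-fold knockout down-regulation are dependent; their
   enrichment among up-regulated genes is the hypergeometric tail.
6. **Enhancer-to-gene assignment.**  Each TF-bound active enhancer maps
   to its nearest TSS within 1,000 kb; gene categories resolve by the
   "any double-positive wins" rule.
7. **Recovery analysis.**  Ectopic C/EBPβ expression in undifferentiated
   cells re-establishes a subset of enhancers; the chain counts which
   reference enhancers regain C/EBPβ, MLL4, H3K4me1 and H3K27ac, split
   into MLL4-premarked and de-novo.

## Worked example

```python
from enact import log10_hypergeom_tail, log10_binomial_tail, percent

# 588 MLL4-dependent genes among 1,302 up-regulated, drawn from 14,902
# expressed genes of which 1,531 are MLL4-dependent (upper tail, phyper
# convention):
log10_hypergeom_tail(14902, 1531, 1302, 588, strict=True)
# -267.8624811478064            (p = 1.4e-268)

# 9,642 of 11,948 MLL4 binding sites on active enhancers, background
# length fraction 0.43:
log10_binomial_tail(11948, 9642, 0.43)
# -1553.567094921208            (p < 1e-300)

percent(5762, 10061)
# 57.3                          (% of C/EBP-bound active enhancers MLL4+)
```

The first number is the log10 probability that at least 588 of 1,302
up-regulated genes are MLL4-dependent by chance — enrichment beyond any
doubt; the second shows MLL4 binding sites concentrate on active
enhancers far beyond their share of regulatory-element length.

An end-to-end run on synthetic data:

```bash
enact simulate --seed 42 --out fixtures/
# then build an analysis.yaml pointing at fixtures/ and:
enact run --config analysis.yaml
```

or in Python:

```python
from enact import SimConfig, write_fixtures, AnalysisConfig, run_pipeline

manifest = write_fixtures(SimConfig(seed=42), "fixtures")
samples = {k: v for k, v in manifest.items()
           if k not in ("chrom_sizes", "annotation",
                        "truth_elements", "truth_genes")}
summary = run_pipeline(AnalysisConfig(
    chrom_sizes=manifest["chrom_sizes"],
    annotation=manifest["annotation"],
    samples=samples, output_dir="out"))
summary["counts"]["islands_mll4_filtered"]   # 122 specific MLL4 islands
summary["counts"]["recovery"]
# {'reference': 85, 'bound': 58, 'mll4': 18, 'recovered': 17,
#  'premarked': 6, 'de_novo': 11}
```

All 122 filtered MLL4 islands coincide with planted MLL4 sites (the 50
planted antibody-artifact sites are removed by the specificity filter),
and the recovery counts match the ground-truth bookkeeping of the
generator.

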