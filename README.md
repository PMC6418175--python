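# ndomics

Analysis toolkit for nitrogen-deprivation (ND) vs nitrogen-replete (NR)
comparative transcriptomics and lipidomics in oleaginous microalgae such as
*Nannochloropsis*. It re-implements, as a tested reusable library, the
bespoke calculations such studies run downstream of read quantification and
lipid identification:

- **Rank-window pathway enrichment** — ESTs are sorted by mean TPM (or by
  the ND/NR ratio of means) and a window of 10% of the list slides in 5%
  steps; each pathway's in-window occurrence *k/w* is compared with its
  background *K/N* via fold = (k/w)/(K/N) and the upper binomial tail
  P(X ≥ k), X ~ Bin(w, K/N), Bonferroni-corrected over all
  (window, pathway) tests. A top-set variant scores categories among the
  *n* most abundant ESTs.
- **Differential expression and EC flux calls** — per-EST fold
  max(r, 1/r) with r = mean<sub>ND</sub>/mean<sub>NR</sub> and a two-sided
  Welch *t* on log2(TPM+1), with optional table-wide Benjamini–Hochberg
  FDR; enzymes with multiple gene copies per EC number are summed
  replicate-wise before the flux direction is called, with per-copy up/down
  counts kept alongside.
- **Lipidomics** — a parser for CLASS(C:D/C:D[/C:D]) shorthand with sn
  positions (TAG sn1/sn3 canonicalized), pathway-of-origin classification
  from the sn2 chain (16:X → plastidic "prokaryotic" route, 18/20/22:X →
  ER "eukaryotic" route), tiered species/class change calls, membrane →
  neutral-lipid signature tracing (exact diacyl match in DAG, embedded
  match in TAG), the prokaryotic fraction of a class's net increase, and
  sn2-PUFA profiling in PC.
- **Cytometry** — spherical cell volume V = πd³/6 from Coulter diameters
  and buoyant density as the midpoint of bracketing sucrose-gradient
  layers.
- **Synthetic data** — seeded generators for expression tables (~12,609
  ESTs, heavy-tailed TPM, ~4.4 gene copies per EC, planted rank-band and
  fold effects) and lipidomes (~80 species in 12 classes, planted
  remodeling) that record their ground truth, so every stage is testable
  without the original sequencing/MS data.

## Worked example

```sh
python examples/lipid_remodeling.py
```

```
lipidome: 85 species, 12 classes

signature traces (source down, target up):
  DGDG(18:2n-6/16:1n-5) -> DAG(18:2n-6/16:1n-5)  [exact-diacyl]  (planted)
  DGDG(18:2n-6/16:1n-5) -> TAG(16:0/16:1n-5/18:2n-6)  [embedded-in-TAG]
  DGDG(18:3n-6/16:0) -> DAG(18:3n-6/16:0)  [exact-diacyl]  (planted)
  MGDG(14:0/16:1n-5) -> TAG(14:0/16:1n-5/20:4n-6)  [embedded-in-TAG]  (planted)
  MGDG(16:0/16:1n-5) -> TAG(16:0/16:1n-5/18:2n-6)  [embedded-in-TAG]  (planted)
  MGDG(20:5n-3/16:1n-5) -> DAG(20:5n-3/16:1n-5)  [exact-diacyl]  (planted)

prokaryotic fraction of the TAG increase: 0.69 (planted 0.7)
```

Each line pairs a galactolipid species whose level falls under ND with a
neutral-lipid species that rises and carries the same sn1/sn2 acyl
signature — evidence that photosynthetic membrane lipids are remodeled into
storage TAG rather than synthesized de novo. The origin fraction (0.69
recovered vs 0.70 planted) says roughly 70% of the TAG gain sits on
species with a 16-carbon sn2 chain, i.e. comes through the plastidic
pathway. The other scripts in `examples/` demonstrate top-set enrichment
(the 175-fold light-harvesting case), sliding-window recovery of a planted
pathway, EC isoform aggregation with opposing copies, and the cytometry
report; `ndomics --help` exposes the same stages as a small CLI, and
`run_pipeline` writes a complete self-describing TSV report bundle.

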