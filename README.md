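# pangei

Comparative microbial genomics at desk scale: codon-usage statistics,
array-CGH segmentation and gene presence/absence calling, pan-genome
core/dispensable partitioning, synteny detection, and composite
genomic-island (GEI) delineation — exercised end to end on synthetic genomes
and simulated CGH panels with planted ground truth.

## The problem

Closely related bacterial strains — for example arsenic-oxidizing
*Thiomonas* isolates from acid mine drainage — can share near-identical
housekeeping genes yet differ by a quarter of their gene content. The
difference concentrates in genomic islands: discrete chromosomal segments
(≈10–200 kbp) of likely horizontal origin, marked by divergent nucleotide
statistics, insertion sequences and integrases, tRNA-gene insertion sites,
and flanking direct repeats (DRs). Comparative genomic hybridization (CGH)
against a reference strain reveals which islands each strain has gained,
lost or duplicated, and partitions the gene set into a *core* genome shared
by all strains and a *dispensable* genome absent or highly divergent in at
least one.

`pangei` packages that whole analysis as a tested Python library, together
with a synthetic-data generator that plants islands and CGH events so every
stage can be scored against known truth.

## What it computes

- **Codon statistics** (`pangei.codon`): relative synonymous codon usage
  over the 57 retained sense codons, RSCU(c) = n_c · k / Σ_fam n, with stop
  codons and the TGT/TGC and AGA/AGG duets excluded; the codon adaptation
  index CAI = exp( (1/L) Σ log w_c ) with w_c = RSCU(c)/max_fam RSCU from a
  highly-expressed reference set; GC3; windowed GC-deviation and GC-skew
  tracks; robust (median/MAD) composition z-scores; correspondence analysis
  of the RSCU matrix.
- **CGH segmentation** (`pangei.cgh`): circular binary segmentation — at
  each step the arc (i, j] maximizing
  |mean(arc) − mean(rest)| / (σ √(1/w + 1/(n−w))) is tested by permutation
  (1000 shuffles, breakpoint added when p < 0.01) — then per-gene status from
  probe-weighted segment means: absent/divergent at log2 ≤ −1, duplicated at
  ≥ +1. Quantile normalization and dye-swap combination are provided.
- **Pan-genome** (`pangei.pangenome`): genes × strains status matrix,
  core/dispensable partition over any strain subset, per-strain flexible
  fractions, hierarchical clustering of strains by status Hamming distance.
- **Synteny** (`pangei.synteny`): orthologs by bidirectional best hit or a
  40% identity / 80% shortest-protein coverage threshold; block chaining with
  a gap parameter of five intervening genes; interval synteny coverage.
- **Island calling** (`pangei.islands`): candidate intervals from runs of
  compositionally anomalous or CGH-variable genes, scored on five criteria
  (composition anomaly, synteny break, mobile-element genes, tRNA 3′
  boundary, 10–112 bp flanking direct repeats); boundaries snap to the DR
  pair when found.
- **Trees** (`pangei.trees`): gap-column filtering (strictly >5% gaps
  removed), p-distances, neighbor joining with deterministic tie-breaks,
  nearest-taxon queries, Robinson–Foulds distance.
- **Simulation** (`pangei.simulate`): annotated genomes with planted
  islands, multi-strain CGH probe panels (Gaussian noise around per-status
  log2 shifts), reciprocal protein hit tables, random additive trees.

## Worked example

```python
from pangei.pipeline import run_pipeline, status_accuracy
from pangei.simulate import SimulationConfig

res = run_pipeline(SimulationConfig(seed=1))
print(res.partition.summary())
print(f"status accuracy: {100 * status_accuracy(res):.2f}%")
for call in res.accepted_islands():
    dr = call.evidence.direct_repeat
    print(call.start, call.end, call.n_criteria_met, dr.length if dr else None)
```

prints

```
{'n_genes': 548, 'n_core': 450, 'n_dispensable': 98, 'core_pct': 82.1,
 'dispensable_pct': 17.9, 'flexible_pct': {'S1': 4.0, 'S2': 10.4,
 'S3': 13.0, 'S4': 0.0}, 'n_unobserved': 0}
status accuracy: 98.77%
36170 66860 5 20
240179 262582 5 35
333547 359838 5 60
439891 458636 5 112
```

548 simulated genes split into 450 core and 98 dispensable (17.9%), the four
planted islands are each called with all five criteria met and their exact
planted direct-repeat lengths (20/35/60/112 bp), and per-gene CGH status
calls recover 98.77% of the planted truth — the residual errors come from a
duplication event whose +1.0 log2 shift sits exactly at the call threshold.
The `examples/` directory holds one narrative script per capability.

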