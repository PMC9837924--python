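# embryodyn

Time-course chromatin and expression dynamics for polyploid embryogenesis.

Allohexaploid wheat embryos pass through eight morphologically defined
stages (DPA 0, 2, 4, 6, 8, 12, 16, 22), during which accessible chromatin is
extensively remodelled: promoter regions open ahead of transcription, and a
transient burst of distal, transposable-element-associated accessible
regions appears mid-embryogenesis together with non-coding RNA expression.
`embryodyn` re-implements the computational layer such a study needs as a
tested, reusable Python pipeline:

- **ACR taxonomy and dynamics** — accessible chromatin regions (ACRs) are
  assigned to genes through a 3 kb-upstream / 2.5 kb-downstream proximity
  window with position priority (promoter > exon > intron > 5'UTR > 3'UTR >
  downstream) and the nearest-gene rule, yielding promoter (pACR), gene-body
  (gACR) and distal (dACR) classes; stage-to-stage gain/loss and
  transient-vs-constant distal calls use the 1-bp overlap convention.
- **Shuffled-background enrichment** — observed/expected overlap ratios
  where the expectation comes from uniform re-placement of query intervals
  into a background domain (intergenic space carrying any epigenetic mark),
  with a pooled Fisher exact p-value.
- **Pseudotime ordering** — a developmental time unit (DTU) per stage from
  cumulative adjacent-sample distances in PCA space rescaled to [0, 10];
  per-gene loess curves on 500 DTU grid points; gene ordering by the angle
  atan2(PC2, PC1) of standardized profiles, which lie on a near-circle for
  phase-shifted genes.
- **Regulatory-network inference** — TF→target candidate edges from motif
  hits inside gene-assigned ACRs, screened by motif enrichment (Fisher,
  p < 0.05) and retained by co-expression (Pearson p < 0.05, positive r),
  with TF-family module collapsing and TF–TF subnetwork extraction.
- **Polyploid triad analysis** — homoeolog (A/B/D) expression-bias
  classification against the seven canonical simplex centroids (balanced,
  dominant ×3, suppressed ×3), hexaploid-vs-ancestor divergence clustering
  (Pearson r, 1-D k-means into dysfunction/middle/conserved), and
  TE-insertion enrichment 1.5–3 kb upstream of the TSS.
- **Statistics** — self-contained Fisher exact, Mann–Whitney U, Pearson
  test, Benjamini–Hochberg FDR and a Welch log2 test, each validated against
  enumeration or permutation oracles in the test suite.
- **Synthetic data with planted truth** — a deterministic generator builds
  a miniature tri-subgenome genome (collinear triads, TEs, stage-resolved
  peak sets, motif hits, negative-binomial counts, ancestor profiles) with
  ground truth for every downstream inference, so the whole pipeline is
  testable offline.

## Worked example

```python
from embryodyn.simulate import SimConfig, simulate_all
from embryodyn.acr import classify_acrs, transient_dacrs
from embryodyn.expression import tpm_normalize
from embryodyn.grn import hits_from_frame, link_tf_targets
from embryodyn.pipeline import merged_acrs

ds = simulate_all(SimConfig(seed=1))
genome = ds.genome

acrs = classify_acrs(merged_acrs(ds.peaks.peaks["ATAC"]), genome)
n = {c: sum(a.category == c for a in acrs) for c in ("pACR", "gACR", "dACR")}
print(f"ACRs: {len(acrs)} total  {n}")

dacr = {s: [a.interval for a in classify_acrs(ds.peaks.peaks["ATAC"][s], genome)
            if a.category == "dACR"] for s in ("DPA6", "DPA8", "DPA12")}
transient, constant = transient_dacrs(dacr["DPA6"], dacr["DPA8"], dacr["DPA12"])
print(f"dACRs at DPA8: {len(dacr['DPA8'])}  transient: {len(transient)}  constant: {len(constant)}")

tpm = tpm_normalize(ds.expression.counts,
                    {g.gene_id: g.span[1] - g.span[0] for g in genome.genes})
hits = hits_from_frame(ds.peaks.motif_hits)
edges = link_tf_targets(sorted({h.motif_id for h in hits}), hits, acrs, tpm)
planted = {tuple(e) for e in ds.truth.edges}
tp = sum((e.tf_gene_id, e.target_gene_id) in planted for e in edges)
print(f"GRN edges: {len(edges)}  precision: {tp/len(edges):.2f}  recall: {tp/len(planted):.2f}")
```

Output:

```
ACRs: 2283 total  {'pACR': 1468, 'gACR': 116, 'dACR': 699}
dACRs at DPA8: 500  transient: 200  constant: 300
GRN edges: 102  precision: 0.95  recall: 0.90
```

The 500 distal ACRs at DPA8 split into the 200 planted stage-specific
(transient) peaks and the 300 peaks shared with DPA6/DPA12 (constant); the
inferred network recovers the planted TF→target edges with high precision
because non-functional motif occurrences fail the co-expression filter.

## Command line

```bash
embryodyn run-all --seed 1 --outdir out          # simulate + full analysis
embryodyn simulate --seed 1 --outdir sim         # synthetic dataset only
embryodyn annotate-acrs --peaks peaks.bed --gff genes.gff3 \
    --chrom-sizes chrom.sizes --out acrs.tsv
embryodyn pseudotime --matrix tpm.tsv --outdir pt
embryodyn grn --hits hits.tsv --acrs acrs.tsv --matrix tpm.tsv --outdir grn
embryodyn triads --matrix tpm.tsv --triad-map triads.tsv --out triads.tsv
embryodyn divergence --matrix tpm.tsv --ancestor anc.tsv --out div.tsv
```

Every output file carries a header comment with the tool version and a hash
of the run configuration; rerunning with the same seed reproduces every
file byte for byte.

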