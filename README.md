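# hicontacts

Significance calling of long-range cis Hi-C contacts, in two modes:

* **regions** — for short regions of interest (1–3 bins), horizontal
  interaction profiles are extracted left and right of the region and each
  contact intensity is tested for enrichment against a background Weibull
  distribution fitted per chromosome and per bin distance (zeros held out as
  a point mass). P-values are BH-FDR corrected per chromosome and replicate;
  with several replicate maps a contact is significant only if its q-value
  passes the threshold in *every* replicate. Consecutive significant partner
  bins of one anchor are reported as clusters.
* **domains** — the bin map is aggregated into an N×N domain-pair contact
  matrix M (domain borders come from an external TAD caller, optionally with
  a hierarchy level). Each pair (i, j) is tested for enrichment over the
  marginal-product null μ_ij = K_i·K_j / 2T under a hypergeometric, Poisson
  or negative-binomial model (dispersion fitted by method of moments with an
  outlier-robust refit), BH-corrected over all pairs.

Also included: PC1 compartment classification (observed/expected →
correlation matrix → first principal component) with majority-vote domain
labels and same-compartment preference tests (chi-square + one-sided
binomial depletion of mixed pairs); cross-tool call-set intersection with
±k-bin tolerance and binomial overlap significance; ChIP-seq peak
enrichment of called partner bins; liftover of output intervals via UCSC
chain files; and a synthetic map generator with planted loops, domain-pair
blocks and compartments for fully self-contained testing.

## CLI

```sh
# region mode: one or more replicate maps (.npy or whitespace text),
# anchors from a BED file or an EnhancerAtlas-style FASTA
hicontacts regions --chr chr1 --map rep1.npy --map rep2.npy \
    --resolution 10000 --regions anchors.bed \
    --alpha 0.01 --window 30 --formats txt,bed,gff --plot --outdir out/

# domain mode: exactly one map plus a domain-border file
# (chrom  start  end  [level]); tests: hypergeometric | poisson | nbinom
hicontacts domains --chr chr17 --map map.npy --resolution 150000 \
    --domains borders.bed --level 0 --test hypergeometric \
    --alpha 0.01 --plot --ticks 10 --outdir out/

# write the synthetic fixture scenario set
hicontacts fixtures --outdir fixtures/ --n-bins 120 --seed 7
```

Region-mode outputs: calls in txt / BED-like / GFF-like formats (the BED
score column is −log10 q capped at 1000), a cluster table, per-anchor
profile plots (distance-weighted intensities and −log10 q with the α
threshold line). Domain-mode outputs: p- and q-value tables, significant
pairs at the threshold, and a triangular figure with the raw map above the
diagonal and −log10 q blocks below it. `--chain <file>` remaps region-mode
output intervals between assemblies.

## Library

Every CLI step is importable: `hicontacts.load_map`, `extract_profile`,
`fit_background`, `profile_pvalues`, `bh_fdr`, `call_interactions`,
`cluster_consecutive`, `aggregate`, `call_domain_interactions`, `pc1`,
`classify_domains`, `compartment_enrichment`, `tolerant_intersection`,
`overlap_significance`, `peak_enrichment`, `generate_map`, …

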