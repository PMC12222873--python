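# gamhap

Haplotype-resolved Genome Architecture Mapping (GAM) analysis toolkit:
from per-sample window coverage tables to phased segregation tables, sample
QC, NPMI contact matrices per haplotype, TAD and A/B compartment calls, and
allele-specific contact / expression / peak statistics — exercisable
end-to-end on a built-in diploid nuclear-slicing simulator.

## What's inside

| module | purpose |
| --- | --- |
| `gamhap.simulate` | Diploid nuclear-slicing simulator: spherical nuclei, ~230 nm slabs, per-cell conformations with planted TADs, compartments, compaction and contact differences; emits coverage TSVs plus full ground truth. |
| `gamhap.phasing` | Positive-window calling via the per-sample optimal coverage threshold (lowest coverage maximizing the neighbour fraction) and window phasing to CAST/S129 with the same threshold. |
| `gamhap.qc` | Sample QC (orphan windows < 60 %, > 50,000 reads, within-plate Jaccard ≤ 0.4), resolution assessment (Kendall τ ≥ 0.95 vs a Yeo–Johnson-transformed Poisson reference), and undersampled-window masking (ND > 5 rule ± 2 flanks, mappability ≥ 0.2). |
| `gamhap.matrices` | Co-segregation counts, NPMI normalization, distance decay/momentum curves, per-distance z-scores, allele-specific contacts (|Δz| ≥ 1, NPMI > 0.3, ≤ 50 Mb) and strong contacts (z > 2, NPMI > 0.3). |
| `gamhap.topology` | Insulation squares (100–1000 kb), TAD borders at 400 kb local minima ± 1 bin, A/B compartments from the O/E correlation-matrix eigenvector oriented by GC, haplotype concordance. |
| `gamhap.allelic` | WDF compaction tracks, ASE calling (binomial vs 0.5, BH, |log2FC| ≥ 1, TPM ≥ 1, total ≥ 20), ChIP peak phasing (|log2FC| > 2, ≥ 10 reads), ATAC D-score permutation calling, promoter states (Active/Inactive/PRC/PRCa), isoform selection, circular permutation tests, E–P / CTCF-loop contact annotation, differential promoter methylation, cryosection allele fractions, 200-kb feature co-occurrence. |

## CLI

Everything is reachable through the `gamhap` entry point:

```sh
# simulate a diploid dataset with ground truth
gamhap simulate --config sim.toml --out simdir --seed 3

# call and phase windows -> unphased/CAST/S129 segregation tables
gamhap phase --coverage simdir/coverage.tsv --out-prefix data

# sample QC report
gamhap qc --seg data.unphased.seg.tsv --reads reads.tsv --out qc.tsv

# NPMI matrices, allele-specific contacts, insulation/borders, compartments
gamhap matrix --seg data.unphased.seg.tsv --resolution 50000 --out-prefix mat
gamhap diff-contacts --seg-cast data.cast.seg.tsv --seg-s129 data.s129.seg.tsv \
    --resolution 50000 --out diff.tsv
gamhap insulation --seg data.unphased.seg.tsv --resolution 50000 --square 400000 \
    --out-prefix ins
gamhap compartments --seg data.unphased.seg.tsv --resolution 100000 --gc gc.bedgraph \
    --out-prefix comp

# allelic feature statistics
gamhap wdf --seg-unphased data.unphased.seg.tsv --seg-cast data.cast.seg.tsv \
    --seg-s129 data.s129.seg.tsv --out-prefix wdf
gamhap ase --counts gene_counts.tsv --out ase.tsv
gamhap phase-peaks --counts peak_counts.tsv --out peaks.tsv --rule chip
gamhap perm-test --features f.bed --targets t.bed --genome genome.tsv
```

A simulator config is a small TOML file:

```toml
window_size = 50000
n_samples = 500
slices_per_sample = 3   # NP multiplex mode
depth = 100

[chrom_sizes]
chr1 = 10000000
```

File conventions: BED-style 0-based half-open coordinates everywhere;
coverage tables are TSVs with columns
`chrom  start  stop  sample  total_cov  cast_cov  s129_cov`; segregation
tables are `chrom  start  stop` plus one 0/1 column per sample; matrices are
exported as window-pair triplet TSVs and tracks as bedGraph.

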