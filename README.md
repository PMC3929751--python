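# cooccur-tfbs

Promoter TFBS enrichment and co-occurrence analysis for matched
two-group expression studies.

Transcription factors rarely act alone: genes driven by the same
regulatory program tend to carry binding sites (TFBS) for the same
small set of factors, close together in their promoters.  This package
implements the corresponding in-silico screen for regulators of a
two-condition response — e.g. non-wounded vs wounded epidermis sampled
from the same donors:

1. **Select** the most strongly regulated genes from a paired log2
   expression matrix: present-call filtering, probe merging, per-gene
   paired t-tests, Benjamini–Hochberg q ≤ 0.05, then the top *N* genes
   by variance (with the fraction of total variance they carry, PCA of
   samples and genes, and a paired SAM statistic as verification).
2. **Scan** each gene's promoter (1500 bp upstream to 500 bp downstream
   of the TSS, both strands) with position-weight-matrix models scored
   Match-style: an information-weighted, min–max-normalised core
   similarity score (CSS, over the 5 most conserved consecutive
   positions) and matrix similarity score (MSS); a hit needs
   CSS ≥ 0.90 and MSS ≥ 0.80 by default.
3. **Test enrichment** of each factor empirically: the observed hit
   count over the gene list is compared to the counts in R = 10⁵
   randomly resampled same-size gene lists,
   p = (1 + #{null ≥ observed}) / (R + 1).
4. **Find co-occurring clusters**: pairs and distinct-factor triples of
   hits whose pairwise start distances all fall within 50 bp, and the
   fraction of the selected genes carrying a triple.

A seeded synthetic-data generator produces ground-truthed inputs —
planted differentially expressed genes and promoters with implanted
three-factor TGTTT-core clusters — so the whole chain is testable
end-to-end with known answers.  See `docs/methods.md` for the model
details and design choices.

## Worked example

The analysis is staged as numbered scripts (each a thin driver over the
library; everything also runs as one command, below):

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_select_genes.py   --seed 1
python analysis/03_scan_promoters.py
python analysis/04_enrich_and_cluster.py --seed 1
```

which prints, with seed 1:

```
planted DE genes: 100 (effect 2.0 log2, noise sd 0.05)
implanted cluster genes: 70 (70% of DE, span <= 50 bp)
...
present-call filter: 2000 -> 1526 genes
q <= 0.05: 105 genes; selected top 100 by variance
selected genes carry 14.5% of total variance; max p among selected = 0.0016
SAM verification: |d|-ranking overlaps the selected set at 97%
recovery: top-100 vs planted DE Jaccard = 0.942
...
enrichment over 2000 -gene universe, R=10000:
  rank 1: FOXO1_SYN observed=750 null_mean=531.9 p=0.0001
  rank 2: FOXO2_SYN observed=749 null_mean=530.5 p=0.0001
  rank 3: FOXO3_SYN observed=659 null_mean=443.2 p=0.0001
  rank 4: DECOY08 observed=290 null_mean=251.3 p=0.0083
co-occurrence: all three factors within 50 bp in 100/100 selected promoters (100%)
```

Reading this: of 2000 genes, the selection stage recovers the planted
100-gene list almost exactly (Jaccard 0.94); the three implanted
forkhead-like factors rank 1–3 among 23 candidates at the resolution
floor of the resampling null (p = 10⁻⁴ at R = 10⁴), clearly separated
from the best decoy; and every selected promoter carries a
three-factor cluster (the 70 implanted ones by construction, the rest
from the AT-rich background — see the methods note on background hit
density at the default cutoffs).

The same run as a single command, plus the individual stage tools:

```bash
cooccur-tfbs run --seed 1 --out results/run        # full pipeline
cooccur-tfbs simulate|select|scan|enrich|cooccur   # single stages
```

Real data drops in the same way: a normalized expression TSV, a design
TSV (sample, group, pair), promoter FASTA (or a genome FASTA plus TSS
table via `extract_promoters`), and JASPAR `.pfm` or TRANSFAC-style
matrix files; `cooccur-tfbs run --config my.cfg` with `mode = real`.

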