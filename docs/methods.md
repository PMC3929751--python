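# Methods

`cooccur-tfbs` implements an in-silico screen for candidate master
regulators of a two-condition transcriptional response: starting from a
paired (matched-donor) expression matrix it selects the most strongly
regulated genes, scans their promoters for transcription-factor binding
sites (TFBS) with position-weight-matrix models, tests each factor for
enrichment against randomly resampled gene lists, and finally searches
for *heterotypic clusters* — sites for two or three different factors
co-occurring within a short window — which are a stronger signature of
coordinate regulation than isolated sites.  A seeded synthetic-data
generator provides ground-truthed inputs so every stage, and the whole
chain, can be validated without external downloads.

## Gene selection

The expression model is a matched two-group design: each donor (pair)
contributes one control and one treated sample, all values on the log2
scale.

1. **Present-call filter.**  Probes must be "present" in at least *k*
   samples (default 3) of *either* group.  When no P/M/A call table is
   available a proxy rule is used: a cell is present iff its log2 value
   is at least 6.0, roughly the intensity floor below which microarray
   signal is indistinguishable from background.  The either/or reading
   is deliberate (a transcript absent before and induced after injury
   must survive the filter); a flag switches to the conjunctive rule.
   Probes with no gene annotation are dropped.
2. **Probe merging.**  Redundant probes of one gene are averaged
   cell-wise (arithmetic mean on the log2 scale), giving one row per
   gene.
3. **Paired test.**  Per gene, a two-sided paired t-test on the per-pair
   differences (treated − control).  With *n* pairs the statistic has
   *n − 1* degrees of freedom; zero-variance differences are a
   degenerate input and raise rather than silently producing p = 0.
4. **Multiple testing.**  Benjamini–Hochberg step-up q-values.  The
   method is deliberately the plain, deterministic BH procedure (not a
   π₀-estimating variant); it is documented and swappable.
5. **Variance ranking.**  Among genes at q ≤ 0.05, the top *N*
   (default 100) by per-gene unbiased variance across *all* samples.
   This matches the variance decomposition used by the PCA below, so
   the reported *variance fraction* — Σ variance(selected) / Σ
   variance(all) — is self-consistent.  Ties break lexicographically by
   gene symbol for reproducibility.  The maximum paired-test p among
   the selected genes is reported (`max_p_in_top`).
6. **PCA.**  SVD of the row-centred matrix; sample scores and gene
   loadings for the first two components, with the sign of each
   component fixed so its loading sum is non-negative.
7. **SAM verification.**  A paired SAM statistic
   d = mean(diff) / (s + s₀) with s = sd(diff)/√n and the fudge factor
   s₀ set to the median of s over genes — a one-line, deterministic
   stand-in for the percentile search; the full search is an obvious
   extension.  The null is sign-flipping of whole pairs.  Note an
   intrinsic small-sample property: with n pairs there are only 2ⁿ sign
   patterns, so the permutation FDR cannot fall below 2·2⁻ⁿ (0.25 at
   n = 3).  The pipeline therefore also reports the overlap between the
   selected set and the top-|d| ranking, which is the meaningful
   verification at small n.
8. **Template matching.**  Pavlidis-style: genes whose profile has
   Pearson |r| ≥ 0.9 with a chosen template gene's profile, split into
   positively and negatively correlated sets.

## Motif models and scanning

A count matrix (JASPAR `.pfm` or a TRANSFAC-style block) is converted
to frequencies with a uniform pseudocount of 0.25 per base
(f = (c + 0.25) / (Σc + 1)), and each position gets an information
weight I(i) = Σ_b f(i,b) · ln(4 f(i,b)) — the KL divergence from the
uniform background, zero exactly for an uninformative column.  The
*core* is the 5 consecutive positions with the largest ΣI (leftmost on
ties); matrices shorter than 5 positions are rejected.

A window is scored by the information-weighted sum Σ I(i)·f(i, bᵢ),
min–max normalised: (Current − Min)/(Max − Min), where Min/Max use the
worst/best base per position.  The consensus word scores exactly 1, the
anti-consensus 0, and an N contributes the position's minimum (an all-N
window can never pass).  Scored over all positions this is the matrix
similarity score (MSS); over the core positions, the core similarity
score (CSS).  These are the established Match-style definitions of
"core score" and "matrix score"; the defaults CSS ≥ 0.90 and
MSS ≥ 0.80 are configuration, not a claim about any particular
published screen's cutoffs.

Scanning slides the window over the promoter and its reverse
complement; a hit needs CSS ≥ cutoff first and MSS ≥ cutoff second.
Reverse-strand hits are reported at their forward-orientation start
(start′ = L_promoter − start_rc − L_motif), so co-occurrence distances
are strand-agnostic.  Overlapping hits, including same-factor overlaps,
are all reported — heterotypic sites sharing a core are expected to
overlap partially.

Promoter coordinates are 0-based, half-open, on the gene's forward
orientation; the default promoter spans 1500 bp upstream through 500 bp
downstream of the TSS (TSS at offset 1500).  When promoters are cut
from a genome, the TSS table is 1-based inclusive, minus-strand
intervals are mirrored and reverse-complemented, and chromosome-edge
overhang is N-padded.  A legacy 1-based position (counted from the
upstream end on "+", from the downstream end on "−") is written
alongside BED output for compatibility with older TFBS reports.

## Enrichment and co-occurrence

Enrichment of a factor in a gene list is assessed empirically: the
observed statistic (total hit count over the list by default;
genes-with-≥1-hit optional) is compared with the same statistic on R
gene lists of the same size resampled uniformly *without replacement*
from the universe of all genes with a promoter record.  Hit counts are
precomputed per gene, so each resample is a table lookup.  The p-value
uses the +1 finite-sample correction,
p = (1 + #{null ≥ observed}) / (R + 1), which keeps p ≥ 1/(R+1) and
makes the null distribution of p slightly conservative (super-uniform).
R defaults to 10⁵; factors are ranked by p, then observed count, then
name.  No cross-factor multiple-testing adjustment is applied by
default (ranked raw empirical p is the output contract); BH across
factors is available as an opt-in column.

Co-occurrence: within one promoter, every pair of hits of the factor
trio whose start distance is ≤ 50 bp, and every triple of hits of three
*distinct* factors with all pairwise start distances ≤ 50 bp.  Distance
is |start − start| (not inner gap), so partially overlapping sites
qualify; a flag switches to gap-based distance.  Reporting is maximal
(every qualifying combination) plus a deduplicated per-gene
`has_triple` flag; the headline statistic is the fraction of the
selected gene list carrying at least one triple.

## Synthetic data: what it emulates and what it does not

* **Expression** — per gene and donor pair, a shared baseline
  ~ Normal(8, 1.5) (donor-to-donor variation, removed by pairing);
  planted DE genes add a fixed effect (default 2.0 log2 units) in the
  treated sample; every cell gets iid Normal(0, noise_sd) measurement
  noise.  The default noise_sd is 0.05, i.e. a paired-difference sd of
  ≈ 0.07.  This is a deliberate power choice made at design time: with
  3 pairs the paired t has 2 degrees of freedom, and a detectable gene
  in such a design necessarily shows |t| in the tens — the regime real
  matched-biopsy datasets exhibit for their top genes.  A pre-hoc power
  analysis shows BH recovery of the planted list collapses entirely for
  paired-difference sd ≳ 0.15 at df = 2, not because of any
  implementation property but because the p-value of a 2-df t-test is
  floor-limited by the sampled variance.  Tests that probe that regime
  (noise_sd = 0.5) document the collapse rather than hide it.
* **Promoters** — iid single-nucleotide background at GC 0.45
  (upstream regions are modestly GC-enriched relative to a ~0.41
  genome-wide average; no dinucleotide or CpG-island structure, since
  the enrichment null resamples gene lists rather than shuffling
  sequence).  Implanted genes (by default 70% of the DE genes) receive
  one *consensus* instance of each of the three factors, random strand,
  mutually non-overlapping, with all pairwise start distances within
  the 50 bp window and clear of the promoter edges.  Consensus (rather
  than matrix-sampled) implants make recovery deterministic at
  MSS = 1.0.
* **Factor panel** — three forkhead-like matrices (length 8–12) share
  the exact TGTTT core block (count 20/0/0/0 per column) with flank
  columns drawn from Dirichlet(0.5) (×20 observations, capped below
  full conservation so the core is strictly the most informative
  window), distinct across factors; decoy matrices are fully random
  with no constructed TGTTT core.
* **Not emulated** — probe-level microarray effects (cross
  hybridisation, saturation), normalisation artefacts, chromatin
  context, conservation, and realistic motif flank information content.
  The last point matters for interpretation: Dirichlet(0.5) flanks are
  much less informative than curated TRANSFAC/JASPAR matrices, so at
  the default cutoffs an exact background TGTTT (probability ≈ 1.3·10⁻³
  per position and strand at GC 0.45) usually survives the MSS filter.
  Background hit density is therefore several sites per factor per 2-kb
  promoter and chance triples occur in most promoters — the per-gene
  `has_triple` flag separates implanted from background genes poorly,
  while the *enrichment* statistic (which compares counts against
  resampled lists and is the screen's actual decision rule) separates
  implanted factors from decoys sharply.  Passing tests demonstrate the
  resampling machinery and the cluster enumeration are correct; they do
  not demonstrate that a triple in a single promoter is specific at
  these cutoffs.

## Reproducibility and numerics

All randomness flows from a single integer seed, fanned out to
per-stage child seeds via `numpy.random.SeedSequence.spawn`; identical
seeds give byte-identical output files.  Resampling is vectorised in
chunks (random-key argpartition) so R = 10⁵ on a 2000-gene universe
runs in seconds.  Deterministic tie-breaks everywhere: leftmost core
window, lexicographic gene order in variance ties, (p, −observed, name)
in factor ranking, (start, strand) in hit ordering.  Degenerate inputs
(zero-variance differences, constant matrices, all-uniform scoring
selections) raise or warn explicitly rather than returning arbitrary
numbers.

Problem sizes used by the test-suite and the acceptance script — a
2000-gene universe, 2-kb promoters, 3 donor pairs, R = 10⁴ resamples,
3 implanted + 20 decoy factors — are the package's default desk-scale
benchmark; they mirror the shape (not the size) of a genome-wide
screen, where the universe is every gene with an annotated promoter
and R = 10⁵.

## Known limitations

* BH is used where the original q-value method behind any given
  published dataset may differ (e.g. π₀-estimating procedures); with
  strong signal fractions BH is the more conservative gate.
* The SAM fudge factor is the median of the per-gene standard errors,
  not the percentile search; at desk scale the difference is
  immaterial, and the permutation-FDR floor at small n (above)
  dominates either way.
* Single-match p-values (TFM-style) are out of scope; the only
  significance statement is list-level enrichment.
* The co-occurrence window statistic is descriptive — no null is
  attached to the per-gene triple fraction.
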