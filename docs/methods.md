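# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open on the plus strand; GFF3 I/O
(1-based inclusive) converts at the boundary, and BED/bedGraph outputs are
0-based natively. Chromosomes are treated as linear: a motif spanning the
origin of a circular chromosome is not reported. This loses at most one
occurrence per motif per replicon and is a documented limitation.

Each motif string is scanned on the plus strand only, overlapping matches
included, and every occurrence is anchored at its methylatable base
(`methylated_position`, `methylated_strand`). The bipartite Type I pair
GGANNNNNNRTGA / TCAYNNNNNNTCC is handled as two separate motifs; their
counts and detected marks are bookkept independently, which makes the
genome-wide mark total an exact sum of per-motif `n_detected`. Palindromic
motifs (GATC, TGGCCA, AGGCCT, CTCGAG, GGCGCC, and CCWGG as a set) have
identical plus- and minus-strand occurrence counts, so the plus-strand
accounting covers the duplex site list with one record per site. A genomic
`N` matches only the motif code `N`, preventing phantom occurrences inside
assembly gaps.

## SMRT methylation calling

Kinetic detection upstream assigns each candidate base a modification QV
(−10·log₁₀ of the detection p-value; QV 30 ⇔ p = 0.001), an IPD ratio and a
coverage. This package consumes those calls (PacBio-style modifications GFF3
or an equivalent TSV) and applies:

- **QV filter**: `qv >= 30`, inclusive, threshold configurable.
- **Assignment**: an occurrence is detected iff a filtered call sits at
  exactly its (contig, methylated position, methylated strand) and the
  call's class is compatible — m6A for A-offset motifs, m4C for C-offset
  motifs, and untyped `modified_base` calls for either (kinetic callers emit
  untyped calls at marginal coverage; excluding them would understate
  fractions).
- **Deduplication**: when several calls land on one (position, strand) in
  one condition, the highest-QV call wins. The choice is arbitrary but
  deterministic; no published rule exists for this edge case.

Summaries report `fraction = n_detected / n_total` per motif × condition,
with means of score, IPD ratio and coverage over *detected* occurrences
only. The report layer rounds half-up — fractions to 3 decimals, means to
1 — matching the conventional presentation of such tables.

## Bisulfite (WGBS) calling

A cytosine is called methylated when coverage ≥ 25× and the proportion of
unconverted reads is ≥ 90%, both inclusive. The proportion test is evaluated
as a comparison of exact rationals (`Fraction(n_meth, n_total) >= Fraction("0.9")`),
so a site at exactly 90% is called identically on every platform and float
representation. The ±20 nt strand-oriented context of each called site (41 nt,
reverse-complemented for minus-strand cytosines, N-padded at contig edges so
record counts stay stable) can be exported as FASTA for external motif
discovery. m5C motif occurrences are then detected by exact position match
against the called set, mirroring the SMRT assignment.

Read alignment, duplicate removal and conversion-efficiency estimation are
upstream concerns; the module starts from the per-cytosine count table.

## Cross-condition comparison

Over one shared occurrence universe, an occurrence detected in all
conditions is *conserved methylated*, in none *conserved unmethylated*
(a "protected" site, presumably occluded by a DNA-binding protein), and
otherwise *differential*. The three classes partition the universe exactly.
A site with no covering call counts as not-detected but is flagged
(`has_data`) so absence of evidence remains visible. Pairwise mark
differences are counted at occurrence level (symmetric by construction),
with the bipartite partners reported both separately and pooled. Stability
across conditions is summarised as the coefficient of variation
(population SD / mean) of the per-motif fraction.

## Promoter classification and enrichment

The methylated base's position is classified as **promoter** if it lies
strictly within 200 bp upstream of any gene's start codon (distance measured
from the base to the first codon base along that gene's upstream direction:
1 ≤ d ≤ 199; d = 200 is excluded), else **gene body** if inside any gene's
[start, end), else **intergenic** (which absorbs regions downstream of
genes). Promoter takes precedence over gene body for overlapping or nested
genes, because the classification targets regulatory regions. When several
genes qualify, the nearest start codon is reported, but any qualifying gene
suffices for the class. Distance is measured from the methylated base rather
than the motif's first base — the base is the mark's actual location; for a
4–6 bp motif the difference is at most a few bp.

Enrichment of a subset (the protected sites) in promoters is tested with a
two-sided Fisher's exact test on [subset vs all occurrences of the motif] ×
[promoter vs elsewhere], computed exactly (hypergeometric enumeration at
fixed margins, summing tables at most as probable as the observed one within
1e−7 relative slack, via `scipy.stats.fisher_exact`). Per-motif p-values are
reported raw; a Benjamini–Hochberg column is available behind a flag but off
by default, matching the single-motif focus of the question.

## Density scanning

Motif occurrences are counted by match start in 1-kb windows sliding every
100 bp. The genome-wide mean per-window count and a dispersion statistic set
the thresholds mean ± k·dispersion (k = 2 by default); significant windows
that overlap or abut merge into maximal regions, whose bounds are the union
of merged windows. Dispersion defaults to the SEM per the method's original
wording, with SD selectable — and the distinction matters: over tens of
thousands of windows the SEM is tiny and k·SEM flags a large fraction of all
windows, while k·SD behaves like a conventional outlier rule. Both modes are
first-class and reported; on the synthetic data the SD mode isolates the
planted GATC-dense kilobase spikes exactly. With homogeneous counts the
dispersion is zero and no region is called. Regions can be labelled against
a user-supplied BED4 catalog (core genome / genomic island / plasticity
region / phage) by majority overlap, defaulting to "core".

## Synthetic data

The generator plants, in a desk-scale random genome, every structural
feature the analysis is meant to recover:

- **Genome**: one 500 kb contig, GC 0.43 (the organism's base composition),
  yielding ≈1,900 GATC, ≈600 CCWGG and tens of occurrences of the rarer
  motifs; 450 non-overlapping genes (lengths ≈ N(900, 250²) bp, floored at
  150) on random strands with multinomially distributed intergenic gaps —
  about 80% coding density, typical of a bacterial chromosome. Two 1-kb
  GATC-dense spikes (40 sites each) exercise the density scan.
- **Methylation truth**: per-motif per-condition Bernoulli states at the
  emulated per-site rates (0.999 for GATC down to 0.940 for GGCGCC,
  following the reference condition of the study's summary tables), sampled
  *per genomic position* so that two motif strings sharing a methylatable
  base never disagree (one kinetic call would serve both).
- **Protected sites**: 22 GATC occurrences forced unmethylated in all
  baseline conditions, 20 drawn from promoter-classified sites and 2 from
  gene bodies; 18 of the 22 are re-methylated in the Dam-overexpression
  condition, against a control condition with the baseline pattern.
- **Condition-pair flips**: the AMP-R-like condition copies the reference
  truth and flips exactly 26/3/2+2/4 detected marks in motifs I, II,
  IIIa+IIIb and IV (the published "4 in motif III" does not split the
  partners; the generator splits them evenly and the comparison reports both
  poolings). Protected and position-shared sites are excluded from the flip
  and protected pools so the planted counts survive assignment exactly.
- **Emission**: methylated positions emit one call with QV ~ N(214, 40²)
  clipped at the detection threshold, IPD ~ N(5.3, 0.7²) and coverage ~
  N(148, 25²) (the study's reference-condition means); unmethylated
  positions emit a sub-threshold call (QV ~ U(5, 25)) with probability 0.5,
  exercising the filter, and protected sites never emit a qualifying call.
  WGBS reports cover every cytosine on both strands with Poisson(50)
  coverage; methylated motif cytosines (and their duplex partners on the
  complementary strand) draw unconverted reads at rate 0.973, everything
  else at a 0.005 conversion-error floor.

A single integer seed is spawned into independent streams (genome, truth,
per-condition SMRT noise, per-condition WGBS noise), so outputs are
bit-reproducible from (seed, config) and stages can be regenerated
independently.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: read-level errors and mapping artifacts,
kinetic-score dependence on coverage and sequence context, partial
(hemi-)methylation, motif-specific QV distributions, off-motif modification
calls (default rate zero), and real genomic structure (repeats, operons,
skew). Recovery results on synthetic data validate the bookkeeping and the
statistics, not the upstream callers.

## Problem sizes and runtimes

The default synthetic genome is 500 kb — large enough that every motif has
tens to thousands of occurrences and every planted count is recoverable with
wide margins, small enough that the full chain (7 SMRT conditions, 2 WGBS
conditions, ≈430,000 cytosine records) runs in a few seconds. Two
scaled-down effects are visible and expected: the 22 protected sites depress
the motif I fraction more than in a full-size genome (0.987 vs 0.999), and
rare motifs (≈60–90 occurrences) show cross-condition CVs above the 0.01
seen at full scale; the tests assert the scale-appropriate versions of these
properties.

## Known limitations

- Circular chromosomes are treated as linear (no wrap-around matches).
- Duplex (hemi- vs fully-methylated) status is not modelled; fractions are
  per motif-string occurrence, one strand each.
- The exact merging convention behind published density-region counts is
  not recoverable from the method description; both dispersion modes and a
  bp-level merge rule are implemented and documented instead of asserting
  equivalence.
- Mismatch-tolerant motif matching and de novo motif discovery are out of
  scope; the context FASTA export feeds external discovery tools.
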