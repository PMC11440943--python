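# Methods

## Scope and model of the assay

`smncall` reconstructs SMN1/SMN2 genotypes from full-length amplicon
long-read (CCS) data and compares them with the two probe-based assays used
in routine spinal muscular atrophy (SMA) carrier screening.  The package
operates on a self-contained synthetic amplicon pair rather than genomic
sequence: every algorithm here depends only on the *relative* structure of
the locus — two near-identical ~3 kb paralogs differing at five fixed bases
(paralogous sequence variants, PSVs) near exons 7 and 8 — so a random
background with the PSVs and a small variant catalogue planted at fixed
coordinates reproduces the problem faithfully while keeping the repository
free of downloads.  The background is generated once from a hard-coded seed;
both references are deterministic.

PSV layout: indices 1–2 in the exon-7 window (index 2 is c.840C/T, the base
that decides which gene a copy functions as), indices 3–4 in intron 7, and
index 5 (c.*239G/A) in the exon-8 window.  The SMN1 pentad is `GCAAG`, the
SMN2 pentad `ATGGA`.  The variant catalogue carries c.-39A>G, the PSV-site
allele swaps c.*3+100A>C, c.*3+215A>G, c.*239A>G, c.*239G>A (display labels
for single-PSV conversions), and the 2-nt deletion c.*237_*238del placed
inside the exon-8 probe window.  Variant names are display labels resolved
through the catalogue, never parsed; coordinates are 1-based on the
amplicon.  The local background around the deletion is pinned to a
non-repetitive heptamer so its alignment placement is unambiguous.

## Read simulation

Reads emulate CCS of the full amplicon: per haplotype, the read count is
drawn `Poisson(copy_number x depth_per_copy)`; each read is the haplotype
sequence with i.i.d. substitution errors (uniform over the three other
bases); reads are then shuffled and renamed so neither names nor file order
leak the origin.  Defaults — `depth_per_copy = 100`, `substitution_error =
0.01` — are the package's standard conditions used by the end-to-end tests
and the acceptance benchmark.  Not modelled (and therefore not exercised by
any passing test): indel sequencing errors, chimeric/PCR-recombinant
molecules, per-base quality variation, barcode demultiplexing, and depth
variation between samples of a pool.  Conclusions from the simulations
transfer to real data only to the extent that CCS consensus error really is
substitution-dominated and small relative to the 20% SNP window.

## Haplotyping

Each read is globally aligned to the SMN1 reference (direct comparison for
equal-length reads, edlib Needleman–Wunsch otherwise); reads under 90%
identity are dropped and counted.  Within a read group, a site is a usable
SNP when its minor-allele frequency — computed over the two most frequent
observations, treating rarer ones as sequencing error — lies in the
inclusive window [0.20, 0.80].  Groups are split on the SNP with the highest
minor frequency (ties to the lowest coordinate) into minor-allele reads
versus the rest, and the procedure recurses with the window re-evaluated
per subgroup (required for nested mixtures such as 1:1:2).  Groups smaller
than `min_group_size = 10` reads are discarded with a count; read
conservation (emitted + discarded + unaligned = input) is asserted by test.
Consensus is per-position majority with ties broken toward the reference;
majority deletions are removed from the consensus string.  The positions
where a consensus differs from the SMN1 reference form the haplotype's
fingerprint, reused by the trio module.

A known boundary case: a haplotype whose true frequency is exactly 0.20
(e.g. one SMN2 copy against four SMN1 copies) is retained only when the
sampled frequency does not fall below the window — at depth 100 per copy
this is close to a coin flip, and the affected copy is then merged into the
major haplotype.  This is a property of the 20% cutoff at finite depth, not
of the implementation; the end-to-end recovery figure is treated as
stochastic for exactly this reason.

## Copy-number calling

Libraries are pooled at equal mass, so total sample depth carries no
copy-number information; only within-sample ratios do.  The relative caller
enumerates copy vectors `c` in `{1..max_copies}^K` (`max_copies = 4`, the
largest copy number observed in the cohort), sets `lambda = N / sum(c)` and
maximises `sum_k log Poisson(r_k; c_k lambda)`.  Exact scale degeneracy
(`c` and `2c` predict identical means) is resolved by minimal total copies
and surfaced via an `ambiguous` flag.  Score ties are detected at 1e-9
log-likelihood tolerance.  When the per-copy depth is known — always true
for simulated batches, and in practice obtainable from batch calibration —
`call_with_depth_prior` assigns each haplotype independently the `c`
maximising `Poisson(r_k; c lambda0)`.  The pipeline uses the depth prior:
it is the only way to resolve collapsed identical haplotypes (two copies in
cis yield one haplotype at twice the depth) and genotypes such as 3:3
whose ratios alone are scale-ambiguous.  The ratio-only caller's recovery
for (1,2) at depth 100 is limited to ~84% by overlap with the 2:3
hypothesis; tests assert it coincides with brute-force maximum likelihood,
while the >=99% recovery property is asserted for the depth-informed call.

## Gene assignment and annotation

The pentad read from a haplotype's consensus decides everything: PSV 2
names the exon-7 gene, PSV 5 the exon-8 gene, and any of PSVs 3–5
disagreeing with the exon-7 gene marks a conversion with region intron 7
and/or exon 8.  A non-canonical base at either gene-defining PSV raises a
dedicated error rather than guessing.  PSV-site mismatches are always
reported as conversion; when the catalogue holds an equivalent variant name
for the swap, that label is echoed too, since the field uses both phrasings
for the same event.  Other differences against the exon-7 gene's reference
are reported by catalogue label when known and by positional `g.` label
otherwise.  Per-sample exon-7/exon-8 copy numbers are the copy-weighted
column sums over haplotypes; an exon-8-converted copy counts toward its
exon-7 gene's exon-7 column and the other gene's exon-8 column.

## Assay simulators

MLPA is modelled as four allele-specific probes (C/T at c.840, G/A at
c.*239) with +/-10 nt windows around the anchors: a copy is counted by a
probe only if it carries the probe allele at the anchor and matches the
background everywhere else in the window, which is how a probe-site variant
(the catalogued 2-nt deletion) silently removes a real copy from the
readout.  Dosage noise is `Normal(0, mlpa_sigma sqrt(true))` — a
counting-statistics heuristic; no published noise model exists for the
kit — and dosages within `gray_band = 0.15` of a rounding threshold are
flagged NLT/NUT (below/at-or-above the threshold).  qPCR reports SMN1 only
(the paralog is chemically blocked) and counts copies by the PSV allele
alone, with discrete +/-1 miscalls at rate `qpcr_miscall` (direction
forcible for deterministic tests) and near-threshold flags at rate
`qpcr_gray`; `cq_to_cn` implements relative quantification against a
two-copy reference, `ratio = 2^(-ddCq)`, call = `round(2 ratio)`.

## Interpretation

Carrier status from SMN1 exon-7 copies: 0 affected, 1 carrier, >=2
negative.  A carrier with >=3 SMN2 exon-7 copies is classed as
conversion-mediated (total copy number preserved), otherwise
deletion-mediated; a negative sample with exactly 2 copies carries a
silent-2+0 risk note.  Cohort tallies report joint genotype ratios to two
decimals, per-gene exon-7 marginals, the carrier rate and a `1/n`-style
prevalence.  The discrepancy taxonomy compares both assays' SMN1 exon-7
calls to the long-read truth: undercalls of a 2-copy sample by qPCR are
false positives for heterozygous deletion (flagged or not); qPCR
undercalls of duplications are false negatives unless the qPCR call itself
was flagged near-threshold; MLPA undercalls of duplications are false
negatives even when flagged (they characteristically sit near the
threshold); remaining flagged disagreements are gray-zone-only.  Unflagged
overcall patterns, which the taxonomy has no dedicated class for, fall
into gray-zone-only as a documented catch-all.

## Trio inference

Fingerprint matching between a child and both parents is exact — CCS
consensus accuracy justifies no mismatch tolerance; near-misses are simply
non-matches.  A child with two copies of a gene whose fingerprints all
trace to one parent is "2+0"; the transmitting parent is "2+0" when those
two copies are its entire complement of the gene.  One copy per parent is
"1+1".  A fingerprint carried by both parents makes the call indeterminate
(never guessed), as does any non-Mendelian (unmatched) fingerprint.  For a
collapsed identical pair (one fingerprint, copy number 2), single-parent
origin is inferred only when the other parent lacks the fingerprint
entirely.  Parents not implicated by child evidence stay at "1+0"/"0+0"
for 1/0 copies and indeterminate for 2 (phase unknowable from one trio).

## Problem sizes and numerical choices

The end-to-end benchmark simulates all 44 reference genotype
configurations at 100 reads per copy and 1% error (~18k reads total) and
re-calls them; it completes in well under a minute on one CPU, and the
property suites (exhaustive partition oracle, brute-force copy-vector
enumeration for K<=4, 1000 simulated trios) are exact rather than sampled
wherever enumeration is feasible.  All randomness flows through
numpy `default_rng` seeds; per-sample seeds are drawn from a single master
seed so any run is reproducible end to end.

## Known limitations

Identical haplotypes in trans vs cis are indistinguishable by sequence;
their resolution relies on the depth prior (copy number) plus pedigree
inference.  The 20% SNP window makes 4:1 mixtures intrinsically marginal
at default depth (above).  MLPA/qPCR noise magnitudes are heuristics, not
fitted to instrument data, so simulated gray-zone rates are illustrative.
The amplicon is synthetic: coordinate-level results do not map onto hg38,
and flanking-gene structure (NAIP/SERF1), exons 1–6, mosaicism and
within-amplicon recombination are out of scope.
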