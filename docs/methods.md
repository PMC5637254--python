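# Methods note

This note records the models, statistical procedures, parameter defaults and
numerical choices implemented in `spliceflank`, and the scope of the
synthetic-data generator used to validate them. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Event model

Transcripts are reduced to sorted, non-overlapping exon intervals in 0-based
half-open genomic coordinates (GTF input is converted on parsing). Within a
gene, transcripts are grouped into *splicing forms* by identical intron
chains; forms are compared pairwise and local differences classified:

- **RI** — one form's intron (s, e) lies inside a single exon of the other
  form, with both boundaries matching exon ends. Inclusion = the retaining
  form.
- **SE** — one form has two introns (s1, e1), (s2, e2) and the other a single
  intron (s1, e2); the exon [e1, s2) is skipped. Inclusion = the form
  containing the exon.
- **A5/A3** — two forms have introns sharing exactly one boundary; the
  non-shared boundaries delimit the alternative segment. The pair only counts
  as an event when that segment is fully exonic in the shorter-intron form;
  without this guard, the intron of an exon-skipping form (which shares each
  boundary with one of the inclusion form's introns) would be misread as an
  alternative-site event. Inclusion = the shorter-intron form (the
  alternative segment is part of its mature transcript). A5 vs A3 is decided
  by which side of the intron varies relative to the strand.

Events from different transcript pairs are merged when (type, chromosome,
strand, anchor coordinates) coincide; inclusion/exclusion sets are unioned.

## Inclusion levels and significance

ψ(event, sample) = ΣTPM(inclusion) / ΣTPM(inclusion ∪ exclusion); 0/0 is
treated as missing. Δψ is the difference of condition means over samples with
defined ψ; if one condition has no defined ψ the event's Δψ is undefined.

An event is *significantly altered* when p < α (strict) **and** total mean
TPM ≥ 10 (inclusive), where total mean TPM is the sum over event isoforms of
the per-isoform mean across all samples.

Tests on the replicate ψ values:

- **Exact permutation test** on |Δψ|: all C(n, n₁) relabelings when that
  count is ≤ `n_perm`, p = (#relabelings with |Δψ*| ≥ |Δψ| − 10⁻¹²) /
  C(n, n₁); otherwise Monte-Carlo with p = (1 + #extreme) / (1 + n_perm),
  seeded. The smallest achievable two-sided p is 2/C(n, n₁): **0.1 at 3 vs 3
  replicates**, so α = 0.05 is unattainable by permutation at that design.
- **Welch's t-test** (unequal variances) on ψ; two constant equal groups give
  p = 1, constant different groups p = 0.
- **`test="auto"`** (default): permutation when 2/C(n, n₁) < α, else Welch.
  This keeps the assumption-free test whenever the replicate count supports
  it and degrades explicitly — never silently — at small n. The choice is
  recorded in the run log.

Null calibration is checked at 5 vs 5 replicates, where the exact permutation
p-values are multiples of 2/252 and P(p < 0.05) = 12/252 ≈ 0.048; the
acceptance suite requires the observed fraction over 500 seeded draws to fall
in [0.03, 0.07], and applies the same band to the chi-squared test on
equal-rate count pairs (2 000 / 20 000 scan positions at rate 0.05, where
expected cell counts are large enough for the asymptotic χ²₁ reference).

## Flank regions

Windows are 50 nt, defined in transcript orientation and reported in genomic
coordinates with sense-strand sequences (reverse-complemented on −):

- A5: upstream exon (UE), alternative segment (ASE), downstream-intron 5' and
  3' ends (DI5, DI3), downstream exon (DE).
- A3: UE, upstream-intron ends (UI5, UI3), ASE, DE.
- RI: UE, ASE (the intron), DE.
- SE: UE, UI5, UI3, ASE (the exon), DI5, DI3, DE.

Across the four event types this yields 20 region classes. When an intron is
shorter than two windows, its end windows are truncated at the intron
midpoint so no intronic position is double-counted; windows are clipped at
gene bounds and flagged. Anchors outside the supplied gene bounds are an
error, not a silent clip.

## Motif statistics

IUPAC patterns are compiled to regular expressions with a lookahead so
overlapping occurrences are counted; `N` in the *sequence* matches no pattern
symbol. Density = count / length × 1000 (per kb). A stratum is compared to
the background by a 2×2 chi-squared test without continuity correction on
(occurrences, scan positions = Σ(L − m + 1)); tables with an empty margin are
flagged degenerate with (0, 1). On uniform random sequence the expected
`GGNGG` density is 4⁻⁴ per position ≈ 3.9/kb, used as the chance reference in
tests. K-mer over-representation uses a +1 pseudocount on background counts
and a binomial upper tail; W-box scans report per-gene presence and a
binomial test of total occurrences against a supplied per-position
background frequency.

## Gene-set operations

Differential-expression filtering: fold ≥ 2 (inclusive) or ≤ 1/2, with
significance < 0.1 (strict); consensus is the direction-wise intersection
across sources. Immunoprecipitation selection requires fold ≥ 2 and
significance < 0.1 in **both** IP lines under every method, then intersects
methods. Overlaps use the two-sided Fisher exact test; term
over-representation uses the hypergeometric upper tail P(X ≥ k); the
intronless share of a set is a plain percentage.

## Synthetic-data generator

Scope: the generator produces annotation-level and quantification-level
fixtures only — a random-base genome, one two-isoform gene per planted event,
isoform TPM tables, and pseudo-pipeline support tables. It does not model
reads (no FASTQ), sequencing error, coverage bias, or inter-gene correlation.

Defaults mirror a typical 3-vs-3 replicate study design at toy scale: 200 genes, 50
events (20 RI / 14 A3 / 10 A5 / 6 SE), 3 vs 3 replicates, planted
Δψ ∈ {+0.4, −0.4}, control ψ uniform in [0.25, 0.75] (shrunk so the mutant
mean stays in [0.05, 0.95]), replicate ψ logit-normal with sd 0.2 around the
condition mean clamped to (0.01, 0.99), gene TPM log-normal(μ=3.0, σ=0.5).
Motif planting counts chance occurrences toward the target and reaches
round(density × length / 1000) occurrences *exactly*, planting instances or
scrubbing by point mutation in sense-strand space while preserving sequence
length and all positions outside the given regions. Support tables plant
fold changes ≥ the planted fold with one-sided multiplicative noise
(sd 0.1 on the log scale) and significance < 0.01, nulls fold ≈ 1 with
uniform significance; a concordance parameter drops each planted gene from
each source independently. Every generator is a pure function of
(config, seed); derived default seeds are config seed + 1 (quantification)
and + 2 (support tables).

## Numerical choices

- Exact permutation enumeration up to `n_perm` = 10 000 relabelings;
  tolerance 10⁻¹² when comparing permuted to observed statistics to absorb
  floating-point ties.
- Chi-squared without Yates correction (large scan-position counts;
  matches the textbook Σ(O−E)²/E identity tested in the suite).
- Fisher and hypergeometric p-values come from `scipy.stats` and are checked
  against full enumeration on universes ≤ 30.
- TSV/JSON outputs are plain text with explicit headers; pipeline data
  outputs are byte-identical under re-runs (the manifest carries the only
  timestamp).

## Limitations

- ψ is computed from isoform TPM, not from junction reads; quantification
  uncertainty is not propagated into the test.
- At 3 vs 3 replicates the Welch fallback relies on approximate normality of
  replicate ψ; its calibration at that n is not separately verified (the
  calibration suite runs at 5 vs 5, where the permutation test is exact).
- Event pairing handles pairwise form differences; complex events that only
  emerge from three-way comparisons (e.g. mutually exclusive exons) are out
  of scope.
- Published headline counts that depend on full-scale external data are
  represented in the acceptance checks by their reported arithmetic and by
  synthetic lists with planted intersections, not by re-analysis of the
  original sequencing data.
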