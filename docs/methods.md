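# Methods

`ampedit` analyses amplicon sequencing of CRISPR/Cas9 editing experiments:
designing ssODN HDR donors that resist re-cutting, quantifying editing
outcomes from reads, summarizing per-site variation at predicted off-target
windows, modelling clone zygosity under donor mixtures, and estimating clone
frequencies from limiting-dilution assays. This note documents the models,
the defaults, and the choices made where the design was genuinely open.

## Coordinates and data model

All internal coordinates are 0-based with half-open intervals; rendered TSV
reports use 1-based inclusive positions. Donors are written in an annotated
string notation: lowercase bases match the reference, UPPERCASE bases are
edits, and `*` marks a phosphorothioate bond between the flanking bases.
Parsing and rendering round-trip byte-identically.

The SpCas9 conventions used throughout: 20-nt spacer (length configurable —
a printed crRNA can admit a 20- or 21-nt protospacer reading, and both are
supported), NGG PAM, blunt cut 3 nt 5′ of the PAM. The cut index is a
between-base index on the amplicon plus strand and is invariant under
reverse-complementing the amplicon.

## Donor design

A designed donor spans `[cut − arm5, cut + arm3)` (defaults 45/45, minimum
arm 20 nt) and carries exactly: the requested payload substitutions, one
PAM-disrupting substitution when requested, and `n` synonymous substitutions
in the PAM-proximal spacer region (default window: the 10 PAM-proximal nt,
the seed region). Synonymous candidates are ranked by
`|usage(WT codon) − usage(alt codon)|` using a bundled human codon usage
table (relative frequency within each synonymous family, normalized at
load); "equivalent-frequency" codons rank first. Ties break toward the PAM.
One edit per codon is enforced so each silent call remains silent in the
final donor. PAM disruption prefers a synonymous change in the GG positions;
when the PAM is coding and no synonymous disruption exists the design fails
unless a non-silent change is explicitly allowed. Phosphorothioate marks
default to 2 bonds per end, mirroring common synthesis practice for
protected ssODN ends.

Validation re-scans the edited allele for a surviving perfect spacer+PAM
match on either strand, checks translation of silent-classed edits,
counts restriction sites gained/lost per enzyme (both strands, palindromes
once), and reports the mismatch count, which equals
`payload + PAM (0/1) + n_silent` exactly.

## Read simulation (what the generator emulates, and what it does not)

The simulator draws full-span amplicon reads from an allele mixture
(multinomial in the mixture fractions), applies a per-base independent
error model — substitutions, geometric-length insertions and deletions,
with the deletion rate multiplied (default ×3) inside homopolymers of ≥3 nt
to caricature nanopore behaviour — and emits Phred+33 qualities from a
clipped normal, independent of the error process. Half the reads are
reverse-complemented by default, as amplicon libraries arrive in both
orientations. True allele labels ride in the FASTQ comment for
truth-tracking; aligners ignore them.

Default "ONT-like" rates are 1% substitutions, 0.3% insertions, 0.5%
deletions (R10-class amplicon reads), quality mean 25 sd 6. The generator
does **not** model signal-level artefacts, chimeras, adapters, barcode
hopping, quality–error correlation, or context-dependent substitution
spectra. Passing tests therefore demonstrate correct counting, filtering and
estimation under a realistic error *rate*, not robustness to every nanopore
artefact class.

## Alignment

The native aligner is a banded dynamic program, local in the read and
reference ("glocal": free reference flanks; read ends soft-clipped exactly
when the score favours it), with a **two-piece gap cost**:
`cost(L) = min(4 + 2L, 20 + 0.25L)` against match +2 / mismatch −4. The
short-gap piece governs 1–9 nt indels; the long-gap piece caps the cost of
large insertions such as a 143 bp synthetic intron so they align as a single
insertion operation instead of truncating the alignment by soft-clipping —
the same rationale as minimap2's dual gap penalty. Scores are kept on an
internal ×4 integer scale so the quarter-point extension stays exact.

The band defaults to `2·|len(read) − len(ref)| + 32` around the main
diagonal, doubles automatically whenever the optimal path touches the band
edge, and small problems (≤4096 cells) use the full matrix outright.
Tie-breaking is deterministic: match before deletion before insertion, best
cell chosen in row-major order. Indels are left-aligned post hoc into
canonical (leftmost) form, and boundary indels created by that shift are
normalized away, so pileup and window-overlap logic see stable coordinates.

Reads are assigned to the best-scoring amplicon over both strands;
the mapping confidence is `min(60, 6·(best − second-best amplicon score))`
(60 when only one amplicon is given), a margin heuristic in place of a
probabilistic mapping-quality model. Reads scoring below 30 are left
unassigned. External alignments can substitute via SAM import, which trusts
the external MAPQ.

## Per-site counting and target summaries

Pileup counting uses the thresholds base quality ≥16, mapping quality ≥10,
and a 10,000-read depth cap (first-come by input order, logged). Reads below
the mapping floor are excluded entirely; base calls below the base-quality
floor are excluded at that site only. Deletions are recorded once at their
left-aligned anchor with their span, while span coverage is tracked at every
deleted position — anchored events serve counting, spans serve the
window-overlap rule. Insertions are anchored after the preceding reference
base (VCF convention) and keyed by inserted sequence; insertion events are
counted from the CIGAR without a base-quality gate. Adjacent mismatches are
counted as independent single-nt substitutions; a pipeline that merges MNPs
would count fewer, larger events.

A target window (default: spacer ∪ PAM of the located guide, padding
configurable) is summarized by counting substitution and insertion alleles
at sites inside the window and deletion events whose span starts in or
extends into it. A variant passes when supported by ≥3 reads and ≥0.1% of
the reads at its site. Under a single-variant-per-read assumption the
fully-reference percentage is 100 minus the sum of passing variant
percentages; when multi-variant reads push that below zero it is clipped to
0 with a warning. Raising either filter threshold can only raise the
fully-reference percentage.

Condition comparisons are two-sided paired t-tests per target with
Benjamini–Hochberg correction across all tests in one invocation;
zero-variance zero-difference pairs give p = 1 by convention. With 3 paired
samples the t-test is exact only under normal differences; at the depths
used in the test suite its realized family-wise error is close to, but not
guaranteed below, the nominal 5%.

## Editing-outcome quantification

Three assay modes mirror common practice:

* **sequence** — per-read classification. The NHEJ window is ±4 nt around
  the cut (configurable; chosen narrow to resist nanopore indel noise, and a
  sensitivity scan over 2–10 nt is recommended for real data). Only indels
  of ≥3 nt inside the window count as NHEJ evidence by default, because 1–2
  nt indels are the dominant nanopore error mode; set `min_indel_len=1` for
  error-free or short-read data. Label precedence is
  NHEJ > HDR_complete > HDR_partial > WT; a read carrying donor bases plus a
  cut-site indel is NHEJ-contaminated and labelled NHEJ. A read must cover
  the window and every donor-edit position with base quality ≥16, otherwise
  it is ambiguous and excluded from denominators (qualities are independent
  of allele, so this exclusion is unbiased). HDR_partial (some but not all
  donor bases) is reported separately and never folded into HDR_complete.
  Fractions carry Wilson 95% intervals.
* **digest (RFLP)** — the fraction of reads containing the intact
  introduced recognition site (e.g. BspEI, TCCGGA), validated to be absent
  from the WT allele; or, from gel band masses, `Σmass(cut)/Σmass(all)`,
  which equals the molar fraction because cutting conserves mass. The
  dilution-series routine (`digest_limit_of_detection`) quantifies the
  assay's limit of detection: at 10,000 molecules the 1% point is recovered
  within ±0.5 percentage points and separated from 0% by a one-sided Fisher
  exact test.
* **size-shift** — the fraction of cut-window-covering reads with a single
  insertion within ±10% of the expected insert length. The default insert
  length is 143 bp (a synthetic intron); descriptions of such inserts are
  sometimes rounded to ~100 bp, so the length is a parameter rather than a
  constant.

## Zygosity mixture model

Each allele of a diploid clone is edited independently with probability
`h`; an edited allele carries the mutant donor with probability `p` (the
mutant fraction of the delivered donor mixture), else the silent donor.
Class probabilities follow by expansion (e.g. mutant/silent heterozygotes
at `2h²p(1−p)`), the bulk mutant allele frequency is `h·p` (linear in `p`
with slope `h`), and the maximum conditional heterozygote fraction among
biallelic-edited clones is 0.5 at `p = 0.5`. Allele independence — no
gene-conversion coupling — is the core assumption. "Heterozygous" is
modelled as mutant/silent biallelic; mutant/WT clones are a separate class,
and both conditional views (among edited clones; among biallelic-edited
clones) are exposed rather than asserting one definition.

The fit is closed-form maximum likelihood: the multinomial likelihood
factorizes into a binomial for edited alleles out of `2n` (giving `ĥ`) and a
binomial for mutant alleles out of edited alleles (giving `p̂`), so profile
95% intervals are independent binomial likelihood-ratio intervals
(χ²₁ cutoff 3.84, found by bisection to 1e-12). Boundary estimates are
flagged. At n = 500 clones the realized per-parameter coverage is ~94–95%.

## Limiting dilution

Wells follow the single-hit Poisson model `P(negative | dose d) = e^{−fd}`.
`f` is the maximum-likelihood estimate found by root-finding on the score
function in `log f` (the log-likelihood is concave, so the root is unique;
xtol 1e-14), which reduces exactly to the closed form
`f̂ = −ln(negative/total)/d` for a single dose. Confidence intervals are
Wald on `log f` from the numerically observed information (common ELDA
practice); all-negative gives `f̂ = 0` with a one-sided likelihood-ratio
upper bound, all-positive is flagged with a lower bound only. Equality of
`f` across groups is tested by likelihood ratio against the pooled fit
(χ² with groups − 1 degrees of freedom).

## Problem sizes in the test and acceptance suites

The suites run entirely on synthetic data at desk scale: the digest
dilution series uses 10,000 molecules × 5 fractions × 10 seeds; the
sequence-mode round trip uses 5,000 reads on a 144-nt amplicon; the
off-target null experiment uses 3 amplicons × 3 paired samples × 2
conditions × 150 reads per sample × 100 seeds; mixture-model recovery uses
500 clones × 100 seeds. These sizes give the binomial bounds quoted in the
tests while keeping each suite to a few minutes.

## Known limitations

* The aligner's band-widening is a heuristic (widen while the optimal path
  touches the band edge); pathological inputs could in principle keep an
  optimal path outside the band without touching it. Small problems avoid
  the issue by using the full matrix.
* The per-site summary decomposes MNPs into single-nt substitutions and does
  not gate insertion events on base quality.
* The single-variant-per-read assumption behind the fully-reference
  percentage under-represents reference reads when multi-variant reads are
  common; the clip-at-zero warning surfaces the broken assumption.
* The error model is deliberately simple (see above); quantitative claims
  about real nanopore runs should be re-validated against matched unedited
  controls, as the off-target comparison does by design.
* The zygosity model ignores clone fitness differences by genotype and
  donor co-delivery kinetics.
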