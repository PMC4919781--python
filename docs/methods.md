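# Methods

## Guide design

A protospacer of matched length L (16–20 nt) is the genomic sequence
immediately 5' of an NGG PAM on the guide strand. `find_pam_sites` is a
complete exhaustive scan: every NGG on the requested strands is reported
(minus-strand PAMs appear as CCN on the sense strand); an optional
`min_flank` filter keeps only PAMs with room for a protospacer. N never
matches and candidate windows overlapping N are skipped with a warning
rather than failing the run, so a masked reference degrades gracefully.

Coordinates are 0-based half-open on the sense strand. A guide's `start`
is the leftmost sense coordinate of its matched protospacer regardless of
strand; its `site_label` is the 1-based sense position of the spacer's
5'-most matched base (strand-aware), with a configurable offset because
published "site N" numbering conventions vary and the one used for the
bundled reporter sites is not documented anywhere we could anchor to.

Three 5'-end policies reflect U6-promoter transcription initiation:
`require_matched_G` keeps only protospacers starting with G; `prepend_g`
tags other protospacers with a mismatched guanine, stored as a lowercase
`g` so tagged and matched guanines are visually distinct (all sequence
comparisons are case-insensitive); `any` emits everything untagged. The
3' G/A preference is recorded as an annotation (`three_prime_pref`), not
a filter — it is a soft design preference, not a validity rule.

The effectiveness flag encodes the observed minimum lengths: inactive
below 17 matched nt, and, for g-tagged guides, below 18 nt total. It is a
prediction of whether a guide is worth cloning, not a measurement.

`truncate_guide` keeps the PAM-proximal suffix, so a truncated guide
shares its PAM, strand and cut site with its full-length parent — the
property that makes 17 vs 20 nt comparisons at "the same site"
meaningful. Cloning oligos follow the fixed Gibson scaffold
`TATATAT...ACACCG + N16–19 + GTTTTAGAGC...`; the scaffold's trailing G
supplies the spacer's first base, so the insert is the spacer minus its
leading G/g and spacers not starting with G/g are refused with a pointer
to the `prepend_g` policy.

## Off-target scanning and the seed window

Off-target candidacy is ungapped: a genomic window counts as a candidate
when an NGG sits 3' of it and its Hamming distance to the matched spacer
is within budget. No DNA/RNA bulges are modelled — the comparison is
positionwise by construction, matching how candidate sites are tabulated
in practice. Two windows are profiled per site: the full matched length
(m20 for a 20-mer) and the 17 PAM-proximal positions (m17). m17 ≤ m20
always; the PAM, including its unconstrained N, is never counted.

The scanner vectorizes the window comparison (numpy sliding windows over
an integer-encoded sequence) and is exact: tests verify set equality with
a brute-force per-position rescan on planted genomes, and recovery of
every planted site with its exact planned mismatch count. Default
mismatch budgets are 5 for ≥20 nt guides and 4 for shorter ones — the
extremes worth examining at each length. NAG PAM scanning exists behind
`include_nag` but is off by default. Overlapping hits on opposite strands
are distinct records; hits are sorted by (record, start, strand).

The bundled benchmark table transcribes the published on/off-target site
set exactly as printed. Two rows are knowingly divergent and covered by
dedicated tests rather than silently corrected: one off-target of the
site-101 guide scores m20=4 by direct Hamming comparison although five
positions are marked mismatched in print (an upstream gapped alignment is
the likely cause), and two of the "4-mismatch" off-targets of the site-42
guide score m17=3 from their printed sequences.

## Indel calling

Clone sequences are globally aligned to the reference amplicon with an
affine-gap Gotoh dynamic program (three states; a length-k gap scores
open + (k−1)·extend). Defaults — match +2, mismatch −4, open −8,
extend −1 — make one k-nt gap cheaper than k scattered mismatches, which
is the right prior for NHEJ alleles; they are configurable via
`AlignScoring`. N is substitution-neutral (score 0). The implementation
is vectorized per DP row; its scores are cross-checked in the tests
against Bio.Align.PairwiseAligner with identical parameters.

Among co-optimal alignments the reported one has every gap run shifted as
far left as possible without changing the score (the same convention as
variant normalization). This makes event coordinates deterministic and
lets round-trip tests demand exact recovery of constructed events.

The cut site defaults to the blunt cut 3 bp 5' of the PAM (between
protospacer positions 17 and 18 of a 20-mer) — standard SpCas9 geometry,
overridable per call since enzymes and nickase setups differ. Only events
whose left edge lies within ±20 nt (default) of the cut are attributed to
the nuclease; more distal events are kept on the clone record as likely
clone-borne polymorphisms. Clones whose aligned identity falls below 0.8
are flagged unalignable and excluded from cohort profiles rather than
mis-called.

Frame class is a function of the summed signed event length: unedited
(no windowed events), in-frame (net ≡ 0 mod 3, including net 0 from
balanced events), frameshift otherwise. Complex alleles contribute each
event to the length bins but one net frame call per clone.

Cohort profiles report deletion/insertion fractions, length bins
{1, 2–8, ≥9} nt (the published binning leaves 9 bp unassigned between
"2–8" and ">9"; we close the gap by putting 9 in the large bin and
document the choice), and both the median and mean event length, since
published summaries have used each. Event and clone counts are reported
separately because a complex allele makes them differ.

## T7E1 quantification

Fraction cleaved is Σcut/(uncut + Σcut) from band intensities; % indel =
100 × (1 − √(1 − f_c)), the standard heteroduplex correction. The forward
map is strictly increasing and convex in f_c with slope 50 at 0, and is
undefined at f_c = 1: a missing uncut band returns f_c = 1 with a
warning, and conversion of real inputs at or above 1 raises. Only
simulated measurements may be clamped (to 0.999999) since Gaussian noise
can push a legal fraction over the boundary. The algebraic inverse
f_c = 1 − (1 − p/100)² round-trips to 1e−9 and is what the simulator
uses. The default ND threshold is 2% indel — conservative, given that
detectable signals in the benchmark table start around 11% — with the
boundary counting as detected; it is a parameter, because the original
detection limit was operational (visible band or not), not numeric.

## Knockout statistics

KO efficiency is the raw reporter-negative percentage. No background
subtraction is applied by default because the operational definition is
the raw FACS gate; `corrected_ko_efficiency` implements
(ko − bg)/(1 − bg) for users who want the ~0.5% background and any
promoter-silencing contribution removed. Group summaries are mean ± SEM
(sample SD/√n; a singleton reports SEM 0 with `sem_defined=False`).
Paired comparisons use Student's paired t or the Wilcoxon signed-rank
test with an exact permutation null up to n = 25 (normal approximation
above); zero-variance differences return a flagged degenerate result
instead of a meaningless statistic. One-way ANOVA covers >2 groups. Star
notation (*/**/*** at 0.05/0.01/0.001) is formatting only.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with ground truth attached; all randomness flows from one explicit seed
(numpy Generator) and outputs are bit-reproducible.

- Edited reads: each read is edited with probability `edit_rate`; events
  are drawn from an `IndelSpectrum` — 80% deletions, truncated-geometric
  lengths of mean ≈5 nt on 1–30 nt, 5% complex (two-event) alleles.
  These defaults emulate the deletion-dominated NHEJ spectrum reported
  for this kind of assay; they are emulation parameters, not measured
  values. Deletion left edges jitter within 8 nt of the cut so events
  stay within the caller's window.
- Planted genomes: uniform-ACGT background (GC fraction is a parameter)
  with non-overlapping NGG-adjacent sites at exactly the planned
  seed-window mismatch counts, mismatch positions uniform within the
  seed window, optional extra PAM-distal mismatches to decouple m20 from
  m17, random strand per site. The default plan used in tests,
  {1:3, 2:9, 3:2, 4:5}, mirrors the benchmark's four category sizes.
- FACS: n_neg ~ Binomial(n_cells, θ + (1−θ)·bg) with bg = 0.5% — the
  unedited reporter line's negative fraction.
- T7E1: the inverse formula plus Normal(0, noise_sd) densitometry noise
  on f_c, truncated to [0, 1).

What the generators do *not* emulate: sequencing errors (Sanger clones
are treated as error-free consensus sequences), PCR chimeras and
amplification bias, microhomology-directed event placement, cell-line
differences in editing outcome, and bulge-mediated off-targets. Passing
recovery tests therefore demonstrates correctness of the computational
pipeline under its own model assumptions, not robustness of the assays to
those real-world artifacts.

## Problem sizes and determinism

The shipped tests and the acceptance script run on desk-scale inputs
chosen to exercise every code path while staying fast: 240 nt amplicons
with 200–500 simulated clones, 30–50 kb planted genomes, 200-seed FACS
replicates, ≤60 nt sequences for the alignment-oracle cross-checks. The
scanner and aligner are exact at any scale; only wall-time motivated
these sizes. Property tests run hypothesis in derandomized mode so the
suite is reproducible run to run.
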