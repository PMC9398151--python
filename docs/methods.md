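# Methods

## Scope and model

`umicall` analyzes molecular-barcoded amplicon libraries for ctDNA
monitoring. The unit of reference is the *panel*: five short amplicons
(65–99 bp) per patient, one carrying the patient's tumor-specific
KIT/PDGFRA mutation and four shared resistance-hotspot assays, each
with its forward primer as an exact amplicon prefix and the top-strand
reverse-primer segment as an exact suffix. All coordinates are 0-based
half-open on the amplicon top strand; VCF export converts to 1-based
with anchor-base padding. Because every target lives on a ≤ 99 bp
amplicon in a closed panel, reads are assigned to assays by their
forward primer (Hamming distance ≤ 2, ties unassigned) instead of
whole-genome alignment; this preserves the decision structure of
"similar alignment" at a fraction of the machinery.

## Consensus construction

Families are keyed by exact `(assay_id, UMI)` string equality — no
fuzzy UMI merging, matching the identical-identifier grouping rule.
A family emits a consensus only with ≥ 3 reads. Columns are those of
the family's modal-length read; length-discordant members are globally
aligned to it (edlib, unit costs — placement differences are
immaterial for column voting) and vote per column, with read bases
inserted relative to the anchor abstaining. A column emits the
majority symbol when its fraction of the family is ≥ `min_agreement`
(default 0.9), otherwise `N`; exact ties always give `N`, never a
base, which is conservative against false calls. Consensus output is
independent of read input order (reads are sorted within families,
families sorted by key).

## Alignment and event model

Consensus reads are aligned to their amplicon by global affine
alignment: match +1, mismatch −1, gap open −2, gap extend −1 (first
gap base −2, each further base −1). Terminal gap runs are trimmed and
treated as coverage loss rather than variants. A free-end-gap
(overlap) formulation was evaluated and rejected: near a sequence end
it trades a real indel for a cheaper mismatch-plus-overhang and so
misplaces variants close to the primers. Consequence: indels whose
left-normalized position is 0 or that abut the amplicon end are not
representable as events; both lie inside primer regions, outside every
target window. Equal-length consensuses with ≤ 2 differences take a
positional fast path (no gapped alignment can score higher there).
Indels are left-normalized by the standard rotate-while-preceding-
base-matches rule, so variant identity is exact tuple equality
`(assay, pos, ref, alt)` — the property the cross-sample rescue rule
depends on. Alignments with < 70% identity are discarded and counted.
`N` positions are excluded from mismatch events and from per-position
depth (they contribute to neither `n_mut` nor `n_total`).

## Calling, rescue, classification

Per target and per observed non-target event inside the target window:
SNV with > 6 supporting consensus reads → `called`; 1–6 →
`provisional`; indel with ≥ 1 → `called`; zero support → `absent`.
The two thresholds are deliberately literal about an asymmetry in the
underlying rules: a solitary SNV call needs ≥ 7 reads while a rescue
anchor needs only ≥ 6 (both configurable: `snv_min`, `rescue_anchor`).
The single-read indel rule admits indel artifacts in principle; the
`indel_min` knob exists for stricter settings, and
`--report-all-events` exposes the full pileup for human review in
place of by-hand alignment inspection. Non-target events are labeled
`novel` and never drive positivity, as do `secondary` variants.

`molecule_count` is defined as consensus depth at the tumor-specific
target position — the locus that governs positivity. A sample is
`positive` if any tumor-specific or resistance variant is called or
rescued; otherwise `negative_low_input` below 50 molecules, else
`negative`. Spike-in consensuses (the diagnostic ATG insertion
immediately after the forward primer, compared by left-normalized
identity) are routed to a counter and excluded from pileups entirely.

## Simulator: what it emulates and what it does not

The generator draws, per assay, `n` input molecules; mutant molecules
are Binomial(n, MAF) (realized counts recorded in the truth manifest);
spike-in counts are taken verbatim (a pipetted control, not a sampled
one). Each molecule gets a UMI uniform over 4^12 (length
configurable; 12 nt is a common hairpin-barcode design choice, not a
value fixed by the protocol), and a family size from a zero-truncated
negative binomial parameterized so the *truncated* mean equals
`family_mean` (default μ = 20, dispersion k = 2 — chosen so that
undersequenced regimes μ < 7 are reachable; the true family-size law
of a given sequencer is not published, so this is a modeling
convention). Reads are `[UMI][amplicon copy]` with i.i.d. per-base
substitutions (default 10⁻³, typical post-filter Illumina scale) and
indels (default 10⁻⁴) outside the UMI; adapters are assumed
pre-trimmed and qualities are constant. Not modeled: PCR-phase errors
propagating into whole families, strand information, quality-score
profiles, UMI errors (available via `umi_error_rate`, default 0).
Passing tests therefore demonstrate the *decision logic* under
idealized noise, not performance on real libraries with correlated
errors.

The qPCR simulator generates the standard curve at threefold dilutions
10 → 0.37 ng with Cq = intercept + slope·log₁₀(q) (+ Gaussian noise,
σ = 0.05 cycles), a long/short quantity pair whose ratio is the
cellular-contamination fraction, and an inhibition control shifted by
a configurable number of cycles.

## QC conventions

Contamination: (long/short)/reference ratio, flagged strictly above
5%. Inhibition categories at shifts ≥ 1 and ≥ 2 cycles are package
conventions (only the category names are prescribed upstream).
Spike-in centering multiplies each raw count by (global median of run
medians)/(run median); low/high flags at 0.25×/4× the global median
are likewise conventions, configurable. Undersequencing is strict:
mean reads per family < 7 over *all* detected families, including
those below the consensus threshold. Standard-curve fits use ordinary
least squares of Cq on log₁₀(quantity); efficiency = 10^(−1/slope) − 1.

## Cohort statistics

Patient positivity = at least one positive sample. The Fisher exact
test enumerates all 2×2 tables with the observed margins using exact
integer weights C(r₁,x)·C(r₂,c₁−x), summing those with weight ≤ the
observed table's (minimum-likelihood two-sided convention — the
dominant software convention; the doubling convention gives ≈ 0.077
instead of ≈ 0.0497 on the headline high-risk table and is **not**
used). t tests are equal-variance Student tests; for log-scale
comparisons, non-detected values (encoded NaN, never 0) are replaced
by half the minimum detected value across both groups before log₁₀.
Imaging concordance treats PD, PR and SD as expected ctDNA-positive
and CR as expected-negative (PR deliberately follows the stated
convention despite being a response category); undefined denominators
are reported as missing.

## Problem sizes and numerical choices

The stochastic test and acceptance workloads use 10,000 molecules ×
20 replicates for the detection limit, 50 × 5,000 molecules for MAF
recovery, and ≥ 10⁵ consensus positions for error suppression —
sizes at which the binomial envelopes being asserted are tight enough
to be informative while a full run stays in the minutes range on one
CPU. Alignment results are memoized per distinct consensus sequence;
pileups use difference-array coverage accumulation. All randomness
flows through a single numpy Generator seeded per sample; identical
(panel, spec, seed) gives byte-identical FASTQ and manifest.

## Known limitations

Amplicon coordinates are not lifted back to genome coordinates. No
duplex/strand-aware consensus, no UMI-network error correction, no
survival analysis. The packaged panel uses invented but structurally
valid sequences (real assay primers are proprietary to the original
design); all tests exercise structure, not the biology of particular
primer sets.
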