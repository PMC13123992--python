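# Methods

## Scope and data flow

The package analyses a tribe-targeted ND2 eDNA metabarcoding survey from
the ASV table onward. Sequencing itself — read QC, trimming, denoising,
chimera removal — is upstream and out of scope; the pipeline's inputs are
(1) reference sequences with lineages, (2) degenerate primer pairs, (3) an
ASV × sample count table with sample metadata, (4) a per-ASV hit table in
BLAST-tabular spirit, and (5) focal-survey and checklist tables. A
synthetic-data generator produces all five with known ground truth.

## In-silico PCR

**Matching rule.** Primer and template symbols are IUPAC base-sets; a
position matches when the sets intersect, and a site's mismatch count is
the number of empty intersections. The budget applies to each primer
separately (forward ≤ m and reverse ≤ m, default m = 2), not to their sum.
Template ambiguity codes are handled by the same rule.

**Product definition.** Coordinates are 0-based half-open on the plus
strand. A plus-strand product runs from a forward-primer site to the end
of a downstream match to the reverse complement of the reverse primer;
primer footprints are included, so length = insert + len(F) + len(R) —
the convention confirmed by the shipped pairs (297+18+17 = 332,
200+18+23 = 241, 179+19+19 = 217). Minus-strand products are found by
scanning the reverse complement and mapping coordinates back.

**Pairing resolution.** When one forward site could pair with several
reverse sites, the shortest legal product is reported (short products
dominate PCR kinetics), and any candidate nested inside another reported
candidate is suppressed. The scan is bounded by `max_amplicon`, default
2 × the pair's expected amplicon — long enough for indel-bearing
templates, short enough to exclude implausible products.

**Implementation and verification.** Sites are found by a vectorised
bitmask scan (A=1, C=2, G=4, T=8; match = nonzero AND). The test suite
checks it exactly against an independent brute-force oracle that expands
every degenerate primer into all concrete sequences and slides them with
plain Hamming distance, over randomized 2-kb references with planted,
mutated, either-strand sites at budgets 0–2.

**Specificity.** `run_insilico_pcr` tabulates the best hit per (pair,
record) and reports amplified species per family/class plus
`pct_target` = 100 · target-family species / all amplified species.
Evaluating primers against a live NCBI snapshot is out of scope; the
reference set is an input.

## ASV processing

**Taxonomy.** Hits are ranked by score, then percent identity; the top
five are kept. Let B be the hits tied at the maximum identity. A single
species in B at ≥ 98% identity gives a species call. Ties collapse to the
lowest common rank of B — genus, then family. A best identity below 98%
never yields a species call: such ASVs fall back to the lowest common
rank of B at genus or coarser (the 98% rule governs species-level calls
only). No common family ⇒ excluded; no hits at all ⇒ excluded. Every ASV
receives exactly one assignment.

**Contamination filter.** For each ASV, sum its reads across the DNA
extraction and PCR blanks (field and filtration blanks are tracked for QC
but do not drive the threshold); the threshold is the mean of the
non-zero sums, or 0 if the controls are clean. An ASV is removed when its
total across *field* samples is strictly below the threshold (whole-ASV
removal, equality retained). The phrase "average of the non-zero summed
control reads" admits a second reading — mean of per-control column
totals — which is implemented as `control_threshold_mode="per_control"`;
the per-ASV reading is the default, and neither is asserted as uniquely
correct.

**Depth standardization.** Each field sample is scaled by
D_min / D_sample, so all field column sums equal the minimum depth
(relative tolerance 1e-6 in the post-condition check). Values stay
fractional; the operation is idempotent. No rarefaction or compositional
transform is offered — proportional scaling is the pipeline's single
normalisation.

**Aggregation and pooling.** Standardized reads are summed over ASVs of a
taxon, then over same-date field replicates (replicates are treated as
additive sequencing effort). Species pairs the marker cannot separate —
mallard/American black duck, tundra/trumpeter swan, greater/lesser
scaup — are summed into pooled taxa on both the eDNA and the survey side
(`pool_community`), so compared vectors share labels. Both steps conserve
grand totals.

**Checklist means.** Per date, species abundance is the mean count over
that date's complete checklists, counting a species absent from a
checklist as 0 (complete checklists report everything observed). The
per-date checklist count is carried along for the ≥ 3-checklist filter.

## Statistics

**Log–log Pearson.** Counts span orders of magnitude, so correlations are
computed on log(x + c) with pseudocount c = 1 by default (configurable;
c = 0 is valid for positive data). The one-tailed p for positive
association uses t = r·√((n−2)/(1−r²)) on n−2 df. Zero variance after the
transform returns an explicitly flagged undefined result — the behaviour
a species with flat read counts triggers — rather than propagating NaN.

**Kendall τ-b** (tie-corrected, via scipy) measures within-date
cross-species concordance; it is invariant under monotone maps, which is
the right property when read counts are at best monotone in abundance.

**Lags.** eDNA integrates recent presence, so reads on sampling date t
are correlated against surveys on t − ℓ for ℓ = 0..5 days: per date
(cross-species τ) and per species (across dates, log–log r). Lagged dates
without surveys are recorded as skips. `best_lag` is the argmax over ℓ of
the mean per-date τ.

**Network.** Nodes are (date, layer) snapshots, layer ∈ {visual, eDNA}.
Candidate edges are visual–visual and visual–eDNA date pairs (eDNA–eDNA
only by flag); an edge is kept when the log–log correlation of the two
community vectors is positive, ≥ 0.6, and one-tailed significant at
α = 0.05. The 0.6 cut is the conventional strong-association screen in
correlation-based ecological networks. Edge sets are monotone in the
threshold by construction.

**Observer comparison.** On dates with ≥ 3 checklists: τ between the
focal survey and each checklist, a percentile bootstrap (1000 resamples
over checklists, seeded) for the mean and 95% CI, τ between standardized
reads and the focal survey, and an indicator of whether eDNA beats the
mean observer. Dates with fewer checklists are excluded.

**Multiplicity.** No multiple-testing correction is applied to the
headline per-species table; a Benjamini–Hochberg column is emitted
alongside for transparency.

## The simulator

**Abundance.** Each species follows a Gaussian passage curve
N(t) = round(peak · exp(−(t−peak_date)²/2w²)) — the simplest shape giving
per-species arrival/departure with two parameters, enough to produce the
early-dabbler/late-diver turnover of a fall stopover. The default roster
has 16 species across the three tribes, peaks from late September to late
November, and peak abundances from 8 to 5000 individuals.

**Surveys.** Observer counts are negative-binomial with mean
p_detect · N and variance m + φm² (Poisson at φ = 0); defaults
p_detect = 0.9, φ = 0.1 — overdispersed counts are the norm for bird
surveys. One exhaustive focal survey per sampling date; 3 checklists per
calendar day from 5 days before the first sampling date, so lagged
analyses have daily coverage.

**References.** One record per species: random flanks (100 nt), an exact
(randomly resolved) forward-primer site of its tribe's pair, an insert of
the pair's stated length, and the reverse complement of a resolved
reverse-primer site. Decoy non-target vertebrates are rejection-sampled
to carry no site within 2 mismatches of any pair.

**Reads.** Expected species shares on date t are proportional to
shedding · Σℓ kernel[ℓ]·N(t−ℓ) with a 6-weight lag kernel over 0–5 days
(default decaying 0.40/0.25/0.15/0.10/0.06/0.04, mass concentrated at
short lags); each species carries 2 ASVs with a fixed Dirichlet haplotype
split; counts per field sample are Dirichlet-multinomial at 650,000 reads
(overdispersion 0.05), exactly multinomial at overdispersion 0. Blanks
receive sparse contamination: each ASV present independently with
probability 0.02 at geometric (p = 0.5) counts, giving a non-degenerate
filter threshold. Hit tables carry the true lineage at ≥ 98.5% identity
plus low-identity filler; distractor branches (tied congeners, sub-98%
bests, cross-family ties) are off by default and switched on per test.

**Randomness.** All draws flow from one root seed through fixed, named
substreams (surveys / references / reads / ASV-split / hits), so each
stage is reproducible in isolation and identical configs give
byte-identical outputs.

**What it does not emulate.** No read-level errors, chimeras or index
hopping (upstream denoising's territory); no hydrological transport,
spatial heterogeneity or eDNA decay kinetics beyond the lag kernel; no
observer heterogeneity beyond a shared dispersion; no taxonomic database
incompleteness. Passing tests therefore demonstrate correctness of the
*analysis* under a fully specified generative model, not field validity
of eDNA abundance inference — on real data, shedding, transport and
marker bias are confounded with abundance.

## Test problem sizes and numerical choices

Simulation-backed tests run at 20,000–200,000 reads/sample on 10 weekly
dates with 10–16 species — large enough that multinomial noise is small
against the tested effects, small enough for a quick suite. Lag-recovery
and network-structure experiments use narrow passage widths (3–8 days)
and staggered peaks: identifiability of a 0–5 day lag requires community
composition to change on that timescale, which wide curves do not.
Calibration checks use 1000 replicates at n = 20 against the 99% binomial
band around α. Tolerances: depth-standardization conservation 1e-6
relative; exact arithmetic asserted exactly; correlation identities to
1e-10 where closed-form, 5e-3 where a +1 pseudocount perturbs an
otherwise exact identity. Ties in hit ranking are broken by stable sort
(score, then identity); date/taxon orderings are lexicographic and
deterministic.

## Known limitations

* The contamination-threshold rule has two defensible readings (per-ASV
  vs per-control averaging); both are implemented, the per-ASV form is
  the default.
* Standardized read counts are a relative signal; the pipeline
  deliberately fits no absolute-abundance calibration model.
* The in-silico specificity statistic is only as good as the reference
  set and its lineages; records missing from the lineage table are
  counted as "unclassified" rather than guessed.
* Replicate aggregation assumes field replicates are exchangeable
  sequencing effort; per-replicate occupancy-style modelling is not
  attempted.
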