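# Methods

This note documents the models and procedures `sidescan` implements,
the defaults it ships, and the design choices made where the underlying
analyses are conventionally done ad hoc.

## Mass screening (`mass_screen`)

Neutral monoisotopic masses are computed from element counts with fixed
atomic constants (C = 12 exactly; H 1.00782503; N 14.00307401;
O 15.99491462; S 31.97207117; P 30.97376200; Fe 55.93493633 Da). Adduct
m/z uses the proton mass (1.00727646 Da), not the H-atom mass, because
m/z is the mass of the charged ion divided by its charge:

- [M+H]⁺ = M + 1.00727646
- [M+2H]²⁺ = (M + 2·1.00727646)/2
- [M−H]⁻ = M − 1.00727646
- [M+Fe−2H]⁺ = M + m(Fe) − 2·m(H) − mₑ = M + 53.9187377

The ferric adduct models an Fe(III) siderophore complex: the metal
coordinates the deprotonated ligand (two deprotonations counted in the
ion formula, Fe³⁺ supplying the remaining charge), leaving a net +1
ion. Screening for it is off by default — seawater siderophore
detections are typically of the apo form, and whether that reflects the
environment or sample processing is an open question — but turning it
on lets apo and ferric detections be separated explicitly.

A feature matches a (compound, adduct) pair when the relative mass
error is at most `tol_ppm` (default 5 ppm, typical for high-resolution
orbitrap-class instruments; configurable). MS² confirmation counts
reference fragments with any observed peak within ±`tol_mz`
(default 0.5 Th, unit-resolution fragment lists). Reference masses are
always recomputed from formulas; a stated mass column is validated to
1 mDa and rejected on disagreement. MS1 peak height is carried as the
abundance proxy; no area integration is attempted.

## Cluster detection (`bgc`)

Petrobactin-like pathways are diagnosed by co-location of PF04183
(NIS synthase) and PF01261 (3-dehydroshikimate dehydratase) hits.
Domain evidence comes from a HMMER domtblout table: hits above the
full-sequence E-value cutoff (default 1e-5, boundary inclusive) are
dropped, then the lowest-E-value hit per (gene, Pfam) is kept.
In published screens the co-localization judgement is usually manual;
here it is codified as a gene-count rule: carrier genes on one contig
join a locus when at most `max_gene_gap` non-carrier genes intervene
(default 3 — authentic clusters are contiguous, and a small gap
tolerates annotation noise). Strand is ignored for grouping because
known clusters mix operon orientations across taxa.

Completeness requires ≥2 *distinct* synthase genes plus a dehydratase
(petrobactin biosynthesis uses two NIS synthases, asbA and asbB; a
single gene with two PF04183 domains counts once). Transporter-like
accessory domains (e.g. TonB-dependent receptors) on or near the locus
(within `max_gene_gap` genes of its edges) are reported but never
required, since their necessity for a functional pathway is not
established.

## ANI and species grouping (`ani`)

Query genomes are cut into non-overlapping 1500 bp fragments per
contig (trailing remainders discarded) — the standard fragment size
for whole-genome ANI. Each fragment is placed by exact k-mer seeding
(k = 16, seeds sampled every 4 bp): shared k-mers vote for a
(contig, diagonal), and the fragment is aligned with edlib in infix
mode against the reference window implied by the winning diagonal,
padded by a 32 bp band. Identity is 1 − edit_distance/1500; placements
below the 80 % mapping floor, or fragments with no shared seed, are
unmapped and excluded. ANI is the mean identity over mapped fragments
×100; the aligned fraction is reported alongside. On substitution-only
divergence this equals a position-by-position comparison almost
exactly (the acceptance run reports the residual, typically <0.001),
which is why the synthetic mutator is substitution-only by default.

Species are connected components (single linkage, the default;
complete linkage available) of the graph with an edge when the larger
of the two directional ANI values exceeds the threshold (default
95 %, the conventional bacterial species boundary; strictly greater
than). Taking the max of the two directions is conservative for
grouping and both directional values are reported.

Two estimators of the complete species genome length from member MAGs
are provided. The default, `completeness_corrected`, averages
length ÷ completeness, which extrapolates each partial assembly to its
complete size — the quantity a species-level RPKM should be
normalized by. The literal product form (mean of length ×
completeness) is retained as `as_printed` for comparability; it
shrinks rather than extrapolates and is not the default.

## Read recruitment and RPKM (`recruit`)

Alignment identity is gap-compensated, 1 − NM/aligned_length, with
aligned_length the read-consuming alignment columns excluding clips;
the aligned fraction is aligned_length/read_length. Records below 95 %
identity or 75 % aligned are removed (thresholds inclusive on the keep
side, since the filter removes records *less than* the cutoffs).
Only primary alignments are counted — competitive mapping assigns each
read once — and each SAM record is one count (mate granularity).
RPKM = count / ((genome_length/10³) × (metagenome_size/10⁹)); the
metagenome size is the total bases of the sample's read set, supplied
via a manifest, because normalization should reflect sequencing effort
rather than the filtered subset. Species-level RPKM sums member-MAG
counts and divides by the species' estimated complete genome length,
recovering reads that overlapping assemblies of one species split
between themselves.

## Growth kinetics (`growth`)

The sliding-window estimator regresses ln(OD) on time in every
contiguous window (default 5 points) and takes the steepest slope
among windows with r² ≥ 0.95; if none qualifies the best-r² window is
used and flagged. Non-positive OD values (blank-subtraction artifacts)
are excluded from log space and counted in the report. Non-positive
best slopes are reported as μ_max = 0 with a non-growth flag. The
logistic fit uses least squares with multiple starting points (K from
the plateau, μ over a coarse grid including 4/span, N₀ from the first
positive reading) and bounds keeping all parameters positive; a series
with no upward trend is a flagged failure. μ_max is scale-free (a
log-slope) and time-shift invariant; K scales with the OD axis.

Strains are compared per condition with an independent two-tailed
Student's t test (pooled variance; Welch's form behind a flag),
significance at p < alpha (default 0.05), no multiple-testing
correction by default, matching how such experiments are convention-
ally reported per condition.

## Synthetic data (`simulate`)

Generators are deterministic given a seed and return ground truth
sufficient to score recovery exactly. Genomes are uniform random
sequence with genes laid left-to-right (lengths 600–1200 bp, gaps
20–200 bp) and the planted cluster occupying consecutive gene slots;
the default cluster mirrors the asb-like operon (asbA/asbB with
PF04183, asbF with PF01261, accessory genes, a TBDT-like transporter).
Mutation is independent per-site substitution to one of the three
alternative bases (indels behind a flag). Reads are uniform with
Poisson count of mean depth·L/read_length and per-base substitution
errors; truth SAM records carry 1-based positions, all-match CIGARs
and NM equal to the injected error count. MS feature tables place one
feature per (compound, adduct) with optional ppm-scale Gaussian mass
jitter; decoys are uniform but resampled until ≥10 ppm from every true
m/z so truth labels are unambiguous. Growth curves are logistic plus
Gaussian noise truncated at zero.

What the simulations do **not** emulate: read-quality models, chimeric
reads, repeat structure or compositional bias in genomes, isotope
envelopes, retention-time structure, or lag phases in growth. Passing
tests therefore demonstrate correctness of the computations under
clean, known-truth conditions, not robustness to every artifact of
real data.

## Problem sizes and numerical choices

Default verification runs use deliberately modest sizes chosen to
exercise every code path with tight statistical expectations: 20
planted-cluster genomes of 60 kbp / 40 genes; species grouping on four
1 %-mutated 60 kbp copies of one ancestor plus one unrelated outgroup
(pairwise within-family divergence ≈2 %, ANI ≈98 %); a 200 kbp genome
vs its 3 %-substituted copy for the ANI oracle; ~5000 error-free
100 bp reads at 10× for recruitment; 100 logistic curves (μ ∈
[0.2, 1.0], noise sd 0.005 OD) for parameter recovery; 1000 null
simulations for the t test's type-I rate. Ties in window selection and
seed voting resolve to the first-seen candidate under a fixed
iteration order, so results are reproducible bit-for-bit for a given
seed.

## Known limitations

- The ANI mapper is exact-seed based; genomes diverged beyond ~20 %
  (or heavily rearranged within a fragment) map poorly — acceptable
  for the >95 % species regime it serves.
- The co-localization gap rule and the E-value cutoff are declared
  defaults, not community standards; both are configurable and should
  be reported with any screen.
- `as_printed` vs `completeness_corrected` genome-length estimators can
  differ by the square of mean completeness; species RPKM values are
  only comparable across studies using the same mode.
- The feature matcher assumes centroided, mass-calibrated feature
  tables; it does no peak picking, isotope scoring or RT alignment.
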