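# Methods

`mapsv` detects structural variants (SVs) from nanochannel optical genome
maps: per-molecule lists of fluorescent label positions marking nicking-enzyme
recognition sites on stretched DNA molecules of roughly 150–400 kbp.  The
package contains a generative error model for such data, a
molecule-to-reference aligner, three statistical SV-calling modules, pipeline
orchestration with mask filtering, and evaluation utilities.  Everything runs
end-to-end on synthetic genomes, so the calling statistics can be validated
against known truth without external data.

## Generative error model

A reference (or mutated haplotype) sequence is digested in silico with the
nicking motif (default GCTCTTC, Nt.BspQI).  Molecules are then imaged under
six error stages, in order:

1. **Sampling.** Molecule start positions are uniform over the genome; length
   is `l0 + Poisson(mu_l)` with `l0 = 150 kbp` (the minimum-length cutoff
   applied by instruments) and `mu_l = 100 kbp`.  Molecules are truncated at
   chromosome ends and read in a random orientation.  In the diploid case
   each molecule comes from either haplotype with probability 1/2.
2. **False negatives.** Each true site drops out independently with
   probability `f_minus` (default 0.12).
3. **False positives.** Spurious labels arise as a Poisson process at rate
   `f_plus` per bp (default 1.2e-5, about one per 100 kbp when scaled to a
   gap).  Drawing a single Poisson(L·f_plus) count with uniform placement
   over the molecule is distributionally identical to per-gap Poisson(d·f_plus)
   draws, because the inter-label gaps (with the two boundary pseudo-labels)
   tile the molecule; the per-gap law is verified by a chi-square test.
4. **Stretch.** One factor `alpha ~ Cauchy(o_alpha = 1, s_alpha = 0.015)` per
   molecule scales every inter-label distance (including the boundary
   pseudo-labels, i.e. a uniform rescaling).  Cauchy draws can be negative or
   absurdly large; we redraw until `alpha > 0` and `|alpha - o_alpha| <= 10
   s_alpha`, since physical distances are positive.
5. **Resolution merging.** Adjacent labels at distance `d` merge to their
   midpoint with probability `1 - 1/(1 + exp(-0.01 (d - d_half)))`,
   `d_half = 1500 bp` being the distance at which the merge chance is 1/2.
   Setting `d_half = 0` disables the stage entirely (the logistic itself does
   not vanish in that limit); this is the switch used for noiseless tests.
6. **Measurement offsets.** Each label moves by Uniform[-e, e] (`e = 50 bp`),
   clipped inside the backbone, with order restored by sorting.

The default rates are set slightly above those of current instruments
(roughly 10% missing labels, one spurious label per 100 kbp) so the callers
are exercised on noisy data.  Each simulated molecule records its haplotype,
source interval, orientation, and realized stretch factor, which enables an
oracle "perfect aligner" used in tests to separate alignment errors from
calling errors.

### Variant injection

`inject_variants` places insertions, deletions, inversions, translocations,
tandem duplications (CNVs), SNVs, and small indels at uniformly sampled,
non-overlapping loci, rejecting placements inside N runs and within 200 kbp
of chromosome ends.  Injected SV loci keep a minimum spacing of 50 kbp (a few
inter-site gaps): two SVs sharing defining nicking sites are not separately
resolvable from inter-site distances by construction of the method, and
would confound per-locus scoring.  Applying the recorded truth list to the
reference reproduces the mutated sequence exactly, which is the invariant the
tests use.  Default large-indel sizes are log-uniform on 2.5–10 kbp, matching
the few-kbp scale of large indels observed in human genomes.  `build_diploid`
starts from (mutated genome, reference) as the two haplotypes; each variant
is copied to the second haplotype with `p_hom = 0.5` (homozygous) and each
remaining variant moves there with `p_het = 0.5`, preserving the total locus
count.

### What the simulator does not model

Chimeric molecules, optical artifacts beyond the six stages, site-dependent
enzyme efficiency, and the repetitive structure of real genomes (the
synthetic reference is i.i.d. random sequence with GC 0.41).  The last point
matters for interpreting results: alignment on a 20 Mbp random genome is
substantially easier than on a mammalian genome, so end-to-end recall here is
an upper bound on real-data behavior (see "Known limitations").

## Alignment

The built-in aligner is a stand-in for the external production aligners.
Seeding matches pairs of consecutive inter-label distances against an indexed
reference gap list (7% relative tolerance plus 300 bp, with a wide-tolerance
retry for heavily stretched molecules); anchor votes are clustered by implied
molecule start, and the best few windows per orientation are extended by a
banded dynamic program over (label, site) nodes.  A matched gap scores a
log-Cauchy density of the relative distance deviation (scale 0.012, chosen at
the sizing-noise scale so a 1–3% deviation outranks a 5–15% one decisively),
floored at -6 so that a gap containing an SV does not break the chain;
skipped sites and labels cost 2.5 each, close to the negative log of the
generative miss/extra probabilities.  Confidence is the total score relative
to the empty alignment, divided by ln 10, so the conventional `confidence >=
9` filter retains alignments with roughly two or more strongly matched gaps
beyond chance; both the pipeline and the second-round split segments apply
that threshold.

Two-aligner integration implements the union/intersection consensus rules
(agreement = same chromosome, reference-interval midpoints within half the
molecule length; the primary aligner's record is kept on agreement).  The
default pipeline runs the built-in aligner once; a second alignment set, for
example parsed from an external aligner's XMAP, can be supplied and is then
integrated.

Two-round split alignment re-aligns the unaligned ends (>= 5 labels) of
partially aligned molecules anywhere in the genome and in either orientation,
producing multi-segment alignments that expose translocation and large-
inversion junctions.

### Register errors and their containment

With exponential-like gap spacing, a one-site register shift is occasionally
score-competitive with the honest assignment — in particular when an
insertion contains a novel nicking site, which acts as a decoy for its right
flank site in every molecule at the locus, i.e. a *correlated* error that
violates the independent-outlier assumption behind the Cauchy likelihoods.
Three containment measures are applied when building size-change evidence:

- the three terminal matched pairs of every alignment are excluded (near a
  chain end there is no flanking context to resolve register ambiguity);
- molecules whose label distance places an end label at a high-support
  cluster of unmatched labels (>= 8 molecules and >= 30% of local coverage —
  the signature of a novel site, not of random false positives) are removed
  as decoy matches;
- a heterozygous/triallelic component must be coherent (at least half its
  members within 3 gamma of the component median) and carry at least
  `max(k_min, 0.2 M)` molecules.  A real allele holds about half the
  coverage, while decoy clusters scale at the miss/extra rates.

## Site-level calling (missing and extra sites)

At a covered reference site, `M` spanning molecules (the site strictly inside
the matched span, since span endpoints are matched by construction) with `m`
carrying a label are scored under three hypotheses: site present on both
chromosomes (binomial with success 1 - fn), absent from both (success fp),
and absent from one (marginalizing the unknown molecule origins with
probability 1/2 each).  The lower-tail binomial p-value and the
null-to-best-alternative likelihood ratio must both clear their thresholds
(defaults 1e-3 and 1e-6, with at least `M_min = 10` covering molecules);
the hom/het comparison decides zygosity, ties going to homozygous.  Extra
sites swap the roles of the null and homozygous-alternative likelihoods and
use the upper-tail p-value.  Candidate extra sites come from unmatched
molecule labels projected onto the reference by interpolation between
flanking matched pairs and clustered within `d_half`.  The per-site
opportunity probability `fp` is derived from the per-bp rate as
`1 - exp(-f_plus * w)` with `w = d_half`, the label-matching window.  All
likelihoods are computed in log space; the heterozygous double sum is checked
against an exhaustive 4^M joint enumeration in the tests.

## Size-change calling

For a pair of reference sites at distance `d0`, every molecule with labels
matched at both sites contributes a distance `d_i`; ratios `r_i = d_i/d0`
are modeled as Cauchy around the allele ratio with a common scale `gamma`
estimated from the pooled data as IQR/2 (Cauchy quartiles sit at location ±
scale; SV loci are a minority so the pooled quartiles track the null).
Tested pairs are all adjacent reference pairs with spanning molecules plus
every span between consecutive matched labels of some molecule (these cover
indels that delete sites or insert new ones).  Five hypotheses are compared —
no indel, homozygous indel (location = sample median of all ratios),
heterozygous insertion, heterozygous deletion, and a triallelic locus — with
the heterozygous/triallelic mixtures reduced from the 2^M subset sum to the
rank-extreme splits `k = k_min .. M - k_min` under the separation assumption
`|r0' - r0| >> gamma`; deletion-side terms whose low-component median is not
below `r0` are dropped, and mirrored for insertions.  A locus is called when
the likelihood ratio of the null to the best alternative is below 1e-6, the
supporting distance change exceeds `delta = 2000 bp`, and (for mixtures) the
component passes the coherence and support-floor guards above.  The size
estimate is the median of the coherent core of the supporting set minus
`d0`; its sign gives insertion versus deletion, and triallelic loci emit two
calls.  Ties among hypothesis maxima break toward the simpler model in the
order hom, het-insertion, het-deletion, triallelic.

`k_min` defaults to 4 with the coverage-adaptive floor `0.2 M` applied at
call time; the fixed floor matters at low coverage, the adaptive one at high
coverage.  The homozygous location uses the sample median rather than a
numeric maximum-likelihood fit; the Cauchy MLE would require solving a
high-degree polynomial for negligible benefit at these sample sizes.

## Complex SVs

**Medium inversions (2–100 kbp).** An inverted segment appears in an
alignment as a window of unmatched reference sites against an equal number of
unmatched labels — a reverse-palindromic CIGAR (`D^k I^k`) — whose label
spacing matches the reference spacing after reversal.  The scan considers
anchor pairs of matched sites with 4–30 interior sites and an interior label
count within [-1, +2] of that (tolerating one missing and two spurious
labels), and compares interior gap sequences with the tolerance rule
`d (1 - e_t) - e_m <= d' <= d (1 + e_t) + e_m` (`e_t = 0.1`, `e_m = 500 bp`);
only interior gaps are compared because the two anchor gaps mirror onto each
other only for symmetric anchor placement.  The reversed matching must be
clean (mean |log ratio| <= 0.05) and clearly better than the forward one
(which must be at least twice as costly): a window that also matches forward
is a symmetric site pattern — intrinsically undetectable on inversion — or a
nearby indel.  Calls need >= 10 supporting molecules and >= 4 interior sites.

**Translocations and large inversions.** Adjacent split-alignment segment
pairs classify by placement: different chromosomes (inter-chromosomal
translocation), opposite orientations on one chromosome (large inversion),
same orientation but non-colinear (intra-chromosomal translocation).
Junction pairs cluster across molecules within 20 kbp — a segment ends at
its last matched site, typically one or two gaps from the true breakpoint —
and clusters with >= 2 molecules are reported.  Zygosity is not called for
complex SVs.

**CNVs.** The genome is tiled with windows of `2 d_half`; window depth is the
number of overlapping aligned molecules.  Windows are grouped by contained
site count (the relevant depth covariate for optical maps), each group is fit
with a Gaussian, and windows with two-sided Z-test p < 0.05 become
candidates.  Windows within one mean molecule length of contig ends are
masked (depth tapers there regardless of copy number).  Adjacent
same-direction candidates merge into blocks; block significance (Stouffer
combination of window Z-scores) must survive Benjamini–Hochberg FDR 0.05
across blocks.  The depth scan is off by default in the pipeline and enabled
when CNVs are expected, because molecule-scale smoothing makes it informative
only for events of a few hundred kbp.

## Pipeline, merging, filtering

The three modules' calls are merged: same-type overlapping calls collapse to
the smallest likelihood ratio; overlapping size-module evidence units
collapse across types to the strongest unit (nested spans re-measure one
event with distorted distances), with the two allele calls of a triallelic
locus kept together; a site-module call overlapping a same-direction
size-module indel is subsumed by it, since size calls carry size estimates.
Mask filtering drops indel calls overlapping N-gaps, fragile sites, or
pseudo-autosomal regions, and complex calls overlapping pseudo-autosomal or
ultra-dense regions (>= 200 kbp at >= 333 sites/Mbp, i.e. mean spacing below
3 kbp).  The run report accounts exactly for per-filter attrition, and the
pipeline is deterministic given its inputs.

## Evaluation

A call is correct when it overlaps (>= 1 bp) a truth variant of the same
mapped type (site-module deletions score against deletion truth, junction
calls check both breakpoints, translocation truth exposes both the excised
span and the paste site); zygosity equality can additionally be required.
The bundled studies widen truth intervals by the localization resolution of
the method: `d_half` for indels (an indel within the merge radius of a
defining site fuses with that site's label, relocating its distance signal
to the adjacent gap) and 30 kbp for junction-type calls (split segments end
at their last matched site, one or two gaps from the breakpoint).
Alignment metrics lift molecule truth coordinates from haplotype to reference
frame through the cumulative indel shifts.  Trio indels integrate by
transitive overlap closure into union-hull loci with per-individual presence.
Mendelian concordance uses the 15-member set O of trio genotype combinations
reachable by biallelic transmission (enumerated and frozen by a test);
expected concordance closes the genotype confusion matrix over a prior SV
probability of 8e-3 (half heterozygous) and evaluates the stated closed forms
for the zygosity-aware and zygosity-ignored definitions, cross-checked by
Monte-Carlo trio simulation.

## Study conditions and problem sizes

The bundled studies (also run by `scripts/acceptance.py`) use a 20 Mbp
single-chromosome synthetic genome at 100x coverage under the default error
model: 75 insertions + 75 deletions (2.5–10 kbp) for the indel studies,
haploid and diploid (`p_hom = p_het = 0.5`); 15 inversions + 15
translocations plus 20 background indels for the complex study.  One study
completes in about a minute on one CPU.  Unit tests use 1.5–4 Mbp genomes.

## Known limitations

- The i.i.d. random reference has no segmental duplications or repeats, so
  alignment ambiguity is far below real-genome levels; end-to-end recall
  (especially for heterozygous insertions) is correspondingly higher than
  would be achieved at full genome scale.
- The aligner is not a reimplementation of any production aligner; its error
  profile resembles the generative model by construction of its scoring.
- Zygosity is not assigned to complex SVs, and CNV copy number is not
  estimated (gain/loss direction only).
- Inversions whose interior site pattern is symmetric under reversal, or with
  fewer than four interior sites, are intrinsically undetectable by the
  medium-inversion test; they are counted against recall, not excluded.
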