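# Methods

## Data model

A study is a loci × samples grid of unordered diploid genotypes over the
allele set {REF, ALT₁..ALTₖ, NULL} plus MISSING. NULL is a real allele —
it participates in genotypes, inheritance and allele frequencies — and
is kept strictly distinct from MISSING (no call at all). Every genotype
carries a provenance flag (`observed`, `imputed_null`, `mendel_recoded`,
`corrected_to_missing`) so each downstream edit can be audited and
reverted. Coordinates are 1-based inclusive externally (VCF convention)
and 0-based half-open internally. Anything non-diploid is a hard error:
the whole model assumes diploidy. Indels are retained as ordinary loci
with multi-character alleles, taken as-called without left-normalization.

Per-locus total depth is the sum of per-sample FORMAT/DP values when the
FORMAT field is present, falling back to INFO/DP; the source used is
logged per file. The coverage filter (default DP ≥ 6,000 summed over
samples, i.e. roughly 70 reads per sample in a ~500-sample study)
refuses to run when depth is unavailable rather than silently passing
everything.

## Null-allele imputation scenarios

Restriction-site loss (point mutation, indel, or methylation of a
methylation-sensitive site) in one species produces a characteristic
signature in a two-species design: missingness md near 1 among the
adults of that species and near 0 in the other. The screen requires
md < 0.05 in one parental species and md > 0.90 in the other, computed
over adults only (hybrids and seedlings never enter the denominator).
Both inequalities are strict: a locus at exactly 0.05 or 0.90 does not
qualify. Four scenarios bracket how much trust to place in the imputed
signal:

* **I** — at each qualifying locus, adults of the high-md species are
  edited: MISSING → {NULL,NULL}; homozygote {X,X} → {X,NULL}.
  Heterozygous calls are left untouched — a genotype that amplified two
  distinct alleles cannot be hiding a dropout copy, and the procedure
  intervenes minimally.
* **II** — Scenario I thinned to at most one imputed locus per fragment,
  limiting the leverage of clustered dropout loci that share one
  restriction-site mutation. Fragments are genes from the annotation, or
  intergenic clusters built by single-linkage on position with gap
  ≤ 10 kb (order-independent, equivalent to a 10-kb sliding window). The
  kept locus is the one with the smallest (chrom, pos) — a deterministic,
  annotation-independent tie-break. Non-imputed loci are never dropped.
* **III** — Scenario I with every `imputed_null` genotype reverted
  ({NULL,NULL} → MISSING, {X,NULL} → {X,X}). Imputation is therefore
  losslessly reversible, and III∘I ≡ identity is enforced by test.
* **IV** — no imputation; every locus with md > 0.90 in either parental
  adult population is discarded. |loci(IV)| ≤ |loci(II)| ≤ |loci(I)| =
  |loci(III)| holds on every input.

Whether estimates under III and IV coincide is checked empirically on
simulated data, never assumed.

## Mother–offspring correction

Seedlings come from known mother trees with unknown fathers. Per
seedling per locus, the observed genotype is tested for Mendelian
compatibility with the mother: some reading of the call must share at
least one allele with her genotype. At imputed loci an apparent
homozygote {X,X} admits the dropout-aware reading {X,NULL}, because a
null copy (maternal or paternal) hides behind the scored allele;
apparent heterozygotes admit no such reading. The direct reading is
preferred whenever compatible (minimal change); a compatible
reinterpretation is applied and flagged `mendel_recoded`; if nothing is
compatible the genotype becomes MISSING (`corrected_to_missing`). A
MISSING mother leaves the offspring untouched, adults are never altered,
and the operation is idempotent. The decision procedure is verified
against exhaustive enumeration over all mother-gamete × offspring-
resolution combinations for every unordered genotype pair over four
alleles plus NULL.

This resolution rule is one consistent reading of "correcting progeny
according to the mother's imputation state"; because every change is
flagged, users can audit or revert it.

## Introgression estimators

All estimators use the supervised admixed Hardy–Weinberg model. Parental
allele frequencies p_I, p_S are estimated from adult *Q. ilex* and
*Q. suber* individuals only — never hybrids or seedlings — with NULL
counted as an ordinary allele. Two tables are kept: raw count fractions
for marker classification, and pseudo-count-smoothed frequencies
(Jeffreys-style 0.5 per allele symbol by default) for likelihoods, which
keeps a genotype that is impossible under both references from sending
the log-likelihood to −∞. An individual with suber contribution
h = q_s draws each allele copy independently from
π_h(a) = h·p_S(a) + (1−h)·p_I(a); the genotype log-likelihood sums
log π_h over the two copies (the 2−δ multiplicity is h-free and
dropped). The likelihood is log-concave in h, so one optimum exists:

* **hybrid_index_ml** — coarse grid (10⁻³) plus bounded golden-section
  refinement; grid ties break toward 0.5. At fully diagnostic loci with
  raw frequencies, the maximizer equals the fraction of suber-origin
  allele copies (closed form used as a test oracle).
* **admixture_em** — per allele copy, responsibility
  w = h·p_S(a)/π_h(a); M-step sets h to the mean responsibility.
  Converges to the same optimum (tolerance 10⁻⁸, max 5,000 iterations;
  non-convergence warns and flags the estimate).
* **admixture_gibbs** — alternates Bernoulli ancestry indicators per
  copy with h ~ Beta(1+n_S, 1+n_I) under a uniform prior; defaults
  mirror a 10,000 burn-in / 100,000 iteration MCMC protocol (thinning
  10), reporting the posterior mean and 90% equal-tailed credible
  interval. Tests and the acceptance script run reduced chains
  (hundreds/thousands of iterations), where the posterior mean already
  agrees with the MLE to ~0.02 on a thousand loci.

Hybrid prevalence (1% vs 10%) is realized as reference-panel
composition in the simulator, not as a prior: the estimators are
supervised and prevalence-free. This differs from Bayesian clustering
tools whose priors see the panel; the package's panel builder exists
precisely to measure whether that composition matters for these
estimators.

Swapping the species labels maps every q_s to 1−q_s. Family summaries
report mean/sd(n−1)/max/min of offspring q_s and of the ratio
r = q_s(offspring)/q_s(mother), with the mother estimated by the same
method and scenario as her offspring (like compared with like; a single
offspring yields sd 0 with a degeneracy flag; a mother with q_s = 0 has
no defined ratio). r > 1 reads as likely cork-oak pollen, r < 1 as
holm-oak pollen, with a configurable ambiguity band (default width 0).

### Hidden dropout in uncorrected individuals

Null-allele imputation edits only parental adults. An F1 hybrid carrying
{X,NULL} at a dropout locus is scored {X,X}, which the likelihood reads
as two copies of the functional-species allele; with most null alleles
on the holm-oak side this shifts uncorrected hybrid q_s upward under
Scenarios I/II. This is a property of the data, not a bug: the scenarios
exist to bracket it (III/IV remove the imputed signal entirely), progeny
correction resolves it for seedlings through the mother, and validation
of estimator accuracy is done on virtual individuals whose null alleles
are explicit, mirroring how simulated reference individuals are built
from allele frequencies.

## Marker classification

Flags are pure functions of population allele frequencies (raw, not
smoothed), hence invariant to sample order. *Discriminant*: the most
common allele in one species has frequency ≥ 0.9 there and ≤ 0.2 in the
other, evaluated in both orientations (symmetric in species); imputed
loci qualify through NULL like any allele. Thresholds are inclusive and
configurable. *Hybrid-pattern*: with distance = maximum absolute
per-allele frequency difference (total-variation-style: simple,
symmetric, bounded), a locus is ilex-like iff d(hyb, ilex) ≤ δ_sim and
d(hyb, suber) ≥ δ_diff, and symmetrically suber-like. δ_sim = 0.1 and
δ_diff = 0.5 are defaults chosen so that a locus behaving as an F1
expectation (intermediate frequencies between fixed parents) is never
flagged; both are mandatory config entries echoed in output headers.
*High imputed frequency*: an imputed locus whose NULL frequency among
adult hybrids is ≥ 0.75 — a candidate methylation-polymorphism
signature; the flag implies imputation by construction. The marker
database is canonical TSV, one row per locus, with an optional
single-table SQLite mirror.

## Linkage anchoring

Homology searching is out of scope; the module consumes 12-column
tabular hit files. Per linkage group, cM is regressed on bp by ordinary
least squares over anchor markers (a "linear function" map; no isotonic
or spline smoothing), with r² reported and groups with fewer than two
distinct-bp anchors excluded. Prediction outside the anchor span
requires explicit opt-in to extrapolate. Each marker is placed by its
best hit — lowest e-value, ties broken by lowest target bp then target
id — after an optional e-value cutoff (the conventional 10⁻⁶ in the
CLI). Placed + unplaced always partitions the markers present in the
hit file; per-group density is count divided by anchor bp span in Mb.

## Simulator

The generator emulates the field design: 99 holm-oak and 98 cork-oak
adults, 22 adult hybrids (simulated as F1s, matching their observed
classification), and open-pollinated hybrid families with the study's
seedling counts (12, 19, 47, 26, 16, 57, 30, 5, 68; 280 total) as
defaults. The locus panel defaults to 1,000 unlinked loci whose
composition mirrors the real marker panel: 20% diagnostic (fixed
alternative alleles), 18% dropout-in-ilex and 3.9% dropout-in-suber
(together the ~21.9% imputed share, with the null-allele excess on the
holm-oak side), the remainder shared biallelic sites with one frequency
per locus drawn from Uniform(0.05, 0.95) and common to both species;
~2.6% of shared loci are written as indels. Dropout alleles are fixed
(frequency 1) in the affected species by default — the screen only
requires near-fixation, and a partial frequency is configurable.
Background per-genotype missingness defaults to 2%, a typical
post-filtering RADseq call-rate loss. The observation model renders
{NULL,NULL} as MISSING and {X,NULL} as {X,X}, exactly the mechanism the
imputation inverts. Read depths are Poisson(70) per called sample, with
a planted subset of loci at Poisson(5) to exercise the coverage filter.

Crosses are Mendelian with unlinked loci (no recombination map: the
model operates on allele frequencies, and no linkage information exists
for this species pair); every allele copy carries its ancestry label, so
each virtual individual has a realized suber fraction, not just a
pedigree expectation. The default category set — pure species, F1, F2,
BC1..BC4 toward each parent, and F1×BCk toward each parent — is one
consistent realization of "two pure plus 18 intermediate categories" and
is fully overridable; expected h follows the recursion
h(X×Y) = (h(X)+h(Y))/2. Open pollination draws each father from a
mixture over the suber/ilex/hybrid pools; the study-level default cloud
(suber 0.7, ilex 0.3) encodes the preferential cork-oak backcrossing the
q-ratio analysis is designed to detect. Reference panels embed n F1
hybrids in round(n/prevalence) individuals, the parental remainder split
evenly with any odd individual to ilex (arbitrary but deterministic).
Everything is a deterministic function of (config, seed); a rerun is
byte-identical.

What the simulator does **not** emulate — linkage and recombination,
genotyping error beyond dropout and uniform missingness, depth-dependent
call quality, selection and mortality, spatial pollen dispersal,
relatedness within pools — bounds what passing tests show: they validate
the algorithms under the stated model, not robustness of the biology to
violations of it.

## Problem sizes and tolerances

The test suite and acceptance script run desk-scale configurations
chosen to make sampling noise negligible relative to the asserted
effects: dropout-recovery on 300–500 loci with 20 adults per species and
no background missingness (where the md estimates are exactly 1 and 0,
and recovery must be exact); estimator checks on 1,000 diagnostic loci
with 20 individuals per category, asserting category means within
2·√(h(1−h)/2L); pollen-cloud checks on 9 families × 50 offspring,
asserting ≥95% of ratios on the expected side of 1; EM–ML agreement at
10⁻⁴; Gibbs–EM agreement at 0.02 with reduced chains. The full-scale
defaults (10⁴ burn-in / 10⁵ MCMC iterations, the complete field design)
remain the library defaults.

## Known limitations

* Null-allele imputation is binary (qualify or not); partial dropout
  with intermediate md in both species is left untouched by design.
* Adult hybrids are never imputed, so their q_s under Scenarios I/II
  inherits the hidden-dropout shift discussed above.
* The background missingness screen can miss a true dropout locus when
  random missingness pushes the low-md species over 0.05 — with 20
  adults a single missing genotype exceeds the strict threshold — so
  recovery guarantees hold only for clean reference panels; larger
  panels relax this.
* The Mendelian filter uses the mother only; it cannot catch errors
  compatible with the mother but impossible under any plausible father.
* Linkage-group placement trusts the homology hits it is given; paralogy
  is only mitigated by the best-hit rule and e-value cutoff.
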