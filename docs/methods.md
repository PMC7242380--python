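# Methods

## Setting and data model

The package models a time series of groundwater samples collected over one
eruption cycle of a cold CO2-driven geyser. The cycle sources three
aquifers: the recovery phase draws intermediate-depth water, minor
eruptions draw deep water, major eruptions draw shallow water. Two coupled
feature tables describe each series: organism abundances (percent relative
abundance of marker-gene scaffolds per sample, columns closed to 100%) and
lipid abundances (percent relative abundance of intact polar lipids, IPLs).
The default design is 14 samples split 6/4/4 over
recovery/minor/major — the scale at which a coupled
metagenome–lipidome series is realistically collected in the field, and the
scale every default threshold below refers to.

## Marker tracking

Organisms are tracked by scaffolds carrying rpS3, a single-copy ribosomal
protein. The rules, in order:

* **Clustering.** Marker amino-acid sequences are clustered greedily at 99%
  identity (collapsing most strains of a species): scaffolds are processed
  by decreasing length, each joining the first cluster whose representative
  it matches at or above threshold, else founding a new cluster. The
  representative is therefore always the longest member. The identity
  metric — which such protocols rarely pin down — is fixed here as global
  alignment identity (match +1, mismatch 0, linear gap −1; identity =
  identical columns / alignment columns, gaps included), computed with
  Bio.Align.PairwiseAligner. Among co-optimal alignments the aligner's
  first is used; on realistic marker sequences co-optimal identities
  rarely differ.
* **Read filter.** Mapped reads with more than 3 mismatches are discarded,
  consistent with the 99% clustering identity.
* **Breadth.** Fraction of scaffold positions covered by ≥1 read, with
  ambiguous bases excluded from numerator and denominator. Undefined (an
  error) when every position is ambiguous.
* **Presence.** A marker is present in a sample if it was assembled there
  or has breadth ≥ 0.95.
* **Abundance.** Percent relative abundance = scaffold coverage / summed
  coverage of all representatives in the sample × 100.
* **Rank from identity.** Best-hit identity ≥99% species, ≥95% genus, ≥90%
  family, <50% phylum/domain. The 50–90% band has no conventional rank in
  this scheme; rather than guess, it is labelled "above-family
  (unresolved)". Clustering operates on amino-acid sequences while read
  mapping operates on nucleotide scaffolds; both sequence spaces are kept
  on the scaffold object.

## Organism–lipid assignment

All organism × lipid pairs among features present in ≥ `min_presence`
(default 7) of the samples are tested with the Pearson correlation; the
two-sided p-value comes from the t distribution with n−2 df. Constant
trajectories are skipped with a warning. Corrections and weighting:

* **Bonferroni.** q = min(1, p·m), with m = the number of pairs actually
  tested after presence filtering (the test universe is not otherwise
  well-defined). The lipid–lipid co-correlation stage uses its own m (its
  number of tested pairs). Bonferroni controls family-wise error, although
  this style of analysis often loosely calls it "false discovery"
  correction; the procedure here is literal Bonferroni.
* **Abundance weighting.** score = q / organism mean percent abundance over
  the analysis samples. Abundant organisms are more likely to leave a
  detectable lipid signal, so at equal significance they are preferred.
* **Assignment.** Per lipid, among records with q < alpha (default 0.005,
  used for both stages), the minimum-score organism wins; ties break by
  lower q, then higher |r|, then lexicographic organism id — a fixed chain
  so runs are deterministic.
* **Roles.** Assigned lipids are *primary*. Non-primary lipids adjacent to
  a primary lipid in the co-correlation graph are *secondary* (inheriting
  that organism); candidates adjacent to primary lipids of ≥2 organisms are
  *unspecific*. Precedence: primary > unspecific > secondary. A lipid never
  carries two organism edges (asserted when the network is built).

Correlations by default span the full common sample set with absences as
0%: the joint absence/presence pattern across aquifer sources is itself
signal. A `copresent_only` flag restricts each pair to samples where both
features are detected, for users who consider absences missing rather than
zero. Whether secondary lipids should additionally be required to be
non-significant against every organism directly is left open by the
procedure's definition; here "not assigned" is the only requirement.

## Isotope mass balances

δ13C values are per mil vs. VPDB. Fractionation is linear by default
(ε = δA − δB); the exact form 1000·((1000+δA)/(1000+δB) − 1) is available
via `mode="exact"`. The two differ by |δA−δB|·|δB|/(1000+δB) — about
0.1‰ at the differences the mixing models see, so the linear convention is
used throughout and mixing is linear in δ (exact mixing is linear in
isotope ratio; the discrepancy is negligible at these magnitudes).

Endmember defaults: ε_CBB = 30‰, ε_rTCA = 12‰ (theoretical pathway
fractionations relative to CO2), ε_WL = 63‰ (DIC-to-lipid fractionation of
the Wood–Ljungdahl pathway as expressed by Altiarchaeum-dominated biomass),
ε_DIC–CO2 = 10‰ (equilibrium at ~15 °C, a parameter here, not computed
from temperature). An optional lipid-vs-biomass offset (default 5‰) is
added to ε_CBB and ε_rTCA when `apply_lipid_offset` is on ("paper mode" in
the CLI, reproducing e.g. the 78% rTCA bound from ε_obs = 20.9‰ against
12+5 / 30+5); it is *not* added to ε_WL, which is already a lipid
(phytane) fractionation. Whether such an offset belongs on the observation
or the endmembers is genuinely ambiguous; applying it to the pathway
endmembers, behind a switch that is off for raw reporting, is this
package's convention.

Both balances are the same algebra: f_A = (B − obs)/(B − A) on whichever
scale (ε for rTCA-vs-CBB, δ for autotrophy-vs-heterotrophy with
δ_auto = δ_DIC − ε_WL and δ_het = the observed bacterial fatty-acid pool).
Observations outside the endmember envelope are clamped to [0, 1] with an
explicit flag rather than rejected — field series routinely exceed
theoretical envelopes — and `series_summary` reports per-sample fractions
plus extrema (the "up to X%" statistics).

## Lipid grammar and membrane profiling

The parser covers acyl lipids `[lyso_|AEG_]C<carbons>:<unsats>-<headgroup>`
and archaeal ether lipids `<n>G-[<m>pentose-][<k>uns-][ext-]AR`. Carbon and
double-bond counts are sums over chains; the detection mode cannot
distinguish a double bond from a cycloalkyl ring, so counts are double-bond
equivalents and each species carries a standing caveat flag instead of a
resolution. The headgroup vocabulary is open: unknown tokens are preserved
verbatim with backbone `other`. Archaeal unsaturation counts >1 parse,
although only k = 1 is attested in the reference table. Canonical names
round-trip the parser exactly over the packaged 107-lipid reference table.

Unsaturation profiles sum percent abundance per double-bond class (0–6 and
an open "7+" class) per sample, restricted by default to diacylglycerol
backbones — the pool whose unsaturation responds to pressure — with a flag
to widen scope, and a second flag choosing whether classes are reported as
percent of all IPLs (default) or re-closed to the restricted pool.
Lysolipid statistics use round-half-away-from-zero to integer percent
(22/72 → 31%).

## Synthetic data and what it does (not) show

The generator plants a fully known truth: organism phase-preference
profiles (preferred phase factor 1.0, others 0.15, lognormal within-phase
detail σ = 0.4, lognormal mean-abundance spread σ = 1), a
production-coefficient matrix mapping organisms to lipids, and per-sample
isotope mixing fractions (shallow-phase samples rich in rTCA-fixed
bacterial carbon, deep-phase samples rich in archaeal autotrophy, δ_DIC
drawn in 3.6–8.0‰ around 5.0‰). Default lipid allocation at 20 organisms /
40 lipids: one primary lipid per organism, 8 symbiont-derived betaine
lysolipids (coefficient 0.2 on the host), 6 shared lipids (equal
coefficients 0.08 on two producers, so the lipid tracks the producers'
unweighted sum), 6 diffuse background lipids (0.04 on four organisms).
Deep-phase producers get polyunsaturated primary lipids (≥7 double bonds),
so the "7+" class peaks in minor-phase samples by construction.

Two deliberate constructions make the zero-noise exactness properties
hold under compositional closure: every organism's coefficients sum to 1,
so the raw per-sample lipid total is constant and closure is a global
scalar; and shared-lipid coefficients are equal across producers. The
single noise knob is multiplicative lognormal σ applied independently to
community and lipidome (plus optional Gaussian ‰ noise on isotopes). All
draws come from `default_rng([seed, stream])` with fixed stream indices
and draw order, so bundles are bit-reproducible across platforms.

Recovery metrics against the planted truth are computed over the planted
primary lipids: recall = recovered producer links / planted links,
precision = correct / assigned among planted primary lipids. A
symbiont-derived lipid is, at zero noise, exactly proportional to its host
(correlation with the host equals its correlation with the host's primary
lipid — the two are indistinguishable by construction), so it is assigned
to the host as primary; such assignments are biologically meaningful but
outside the planted primary set, and are therefore not counted against
precision. This is a real limitation of correlation-based role
classification, not of the generator: primary/secondary separation relies
on noise structure (lipid-level dynamics decoupling from DNA-level
dynamics) that the generator only produces at σ > 0.

What passing tests do not show about real data: the generator draws
independent lognormal noise per cell, while real lipidomes have correlated
extraction/ionisation effects per sample; turnover-time mismatches between
DNA and lipids (slow-cycling archaeal ether lipids especially) and cell
lysis during filtration can decouple trajectories in ways no multiplicative
noise reproduces; and the synthetic lipidome has far fewer features than a
real one (~300 IPLs), so real multiple-testing burdens are heavier.

## Numerical choices and degenerate inputs

Pearson r is clamped to [−1, 1]; |r| = 1 maps to p = 0. Constant vectors
raise a dedicated error and the offending pair is skipped with a warning.
All-zero samples stay zero under closure (logged). Zero-abundance organisms
cannot be scored and are skipped. Mixing with equal endmembers is an error;
out-of-envelope observations clamp with a flag. δ13C outside (−120, +50)‰
is rejected as implausible at record construction. Tables are validated on
construction (no duplicates, no negatives, no NaN).

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale — 14
samples, up to 20 organisms and 40 lipids for recovery checks, ≤8×12
feature grids for the 200-case brute-force equivalence sweep, 1000 random
profiles for the breadth oracle — sizes chosen so the full suite completes
in well under a minute while still exercising every rule at the study's
own sample count.
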