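# Methods

This note documents the models, statistics and numerical choices behind
famshare, in the order the pipeline runs them, and states what the
synthetic-data generator does and does not emulate.

## Data model

An `OtuTable` is an OTUs × samples matrix of non-negative integer read
counts with optional greengenes-style 7-rank taxonomy per OTU; trees are
rooted scikit-bio `TreeNode`s with finite non-negative branch lengths;
per-sample metadata carry host, household, body site, species, role,
age (years, fractional), pet-ownership flags and household size.  Role
and age must be mutually consistent: infant 0–1 y, child 1–17 y, adult
18–59 y, senior ≥ 60 y.  Paw sites are restricted to dogs and palms to
humans; forehead, tongue and feces are valid for both species.  Sample
and OTU order is preserved as read and never encodes meaning.

## Synthetic cohort generator

The generator exists so every downstream stage can be exercised, and
its parameters recovered, without sequencing data.

**Roster.**  Four household types (with children / with dogs / with
both / with neither), 17/17/8/18 by default for 60 households.  Every
household has one couple (`adult_M` + `adult_F`, ages drawn Uniform(26,
55)); child-bearing households draw 1–3 offspring with ages
Uniform(0.5, 18) (role `infant` below one year); dog households draw
1–2 dogs.  Humans contribute 5 samples (feces, tongue, forehead, two
palms), dogs 7 (feces, tongue, forehead, four paws).

**Counts.**  A four-level hierarchical Dirichlet-multinomial:

1. *Site baselines.*  Sites are grouped into human gut / human oral /
   human skin / dog gut / dog oral / dog skin; each group gets a
   baseline composition β ~ Dirichlet(κ_site · w) with κ_site = 50 and
   w a weight vector favouring the group's characteristic taxonomy
   families (Propionibacteriaceae / Streptococcaceae /
   Staphylococcaceae on human skin, gut anaerobe families in feces,
   oral families on the tongue).  Dog-surface baselines use a 10×
   concentration on flat weights so they come out even and diverse
   relative to the dominated human skin profile — mirroring the
   observation that dog skin communities are flatter than human ones.
2. *Household profiles.*  Per household and site group,
   φ ~ Dirichlet(κ_family · β) with κ_family = 30.  Setting
   κ_family = inf collapses φ to β — the switch used by the null
   configuration (`SimulationConfig.null()`), which also zeroes all
   mixing weights.
3. *Individual targets.*  Adults mix the household profile with a
   couple-shared latent draw ψ ~ Dirichlet(κ_spouse · β):
   target = (1 − w_sp)·φ + w_sp·ψ, w_sp = 0.35 by default.  The shared
   draw, rather than profile copying, makes couple similarity
   continuously tunable, which is what the parameter-recovery tests
   exploit.  κ_spouse (default 30) is a separate knob so the couple
   draw stays well defined when the household effect is switched off.
   Offspring mix toward an infant signature ι (half of its mass on
   Streptococcaceae-labelled taxa, half the site baseline) with weight
   exp(−age/τ), τ = 1.5 y, on top of a parent-child mix w_pc = 0.2 of
   the couple draw.  Human skin targets in dog-owning households mix in
   w_dog = 0.15 of a dog-surface donor profile restricted to taxa below
   the median human-skin baseline mass — a rare-taxon effect, visible
   to presence-based (unweighted) distances and nearly invisible to
   abundance-weighted ones, which is how the dog effect behaves in real
   skin data.
4. *Profiles and reads.*  Individual profile ~ Dirichlet(κ_individual ·
   target) with κ_individual = 200; read depth ~ lognormal(log 20000,
   0.6) truncated to ≥ 1 (set sdlog = 0 for fixed depths); counts ~
   Multinomial(depth, profile).

All draws flow from a single integer seed; identical configs give
byte-identical artifacts.

**What the generator does not emulate.**  No sequence-level noise (PCR
bias, chimeras), no strain dynamics, no longitudinal sampling, no cat
microbiota (ownership is a flag only), and no senior hosts in the
default roster.  At the default κ_family = 30 the household effect is
strong relative to the real data — observed couple R saturates near 1
rather than the 0.2–0.6 range typical of field studies — so passing
recovery tests demonstrate correct machinery and monotone parameter
response, not field-realistic effect sizes.  Recovery tests therefore
isolate one effect at a time (κ_family = inf with a single mixing
weight active).

## Phylogenetic metrics

All metrics are computed from a *branch partition*: for every non-root
branch, its length and the set of OTUs below it.  A sample "has" a
branch when ≥ 1 of its reads maps below it.

* *Unweighted UniFrac* = (branch length unique to one sample) /
  (branch length observed in either).  Presence is count ≥ 1 after
  rarefaction; there is no relative-abundance floor.
* *Weighted UniFrac* (raw) = Σ_b ℓ_b |p_i,b − p_j,b| with p the
  fraction of a sample's reads below branch b.  The normalized variant
  divides by Σ_tips depth(tip)·(p_i,tip + p_j,tip).  Raw is the
  default; both are exposed because published pipelines differ.
* *Faith's PD* is the total branch length of the subtree spanning the
  observed tips **and the root** (stated explicitly; implementations
  differ).  An empty sample yields PD = 0 with a warning rather than an
  error so rarefaction curves stay total.
* *Rarefaction* subsamples without replacement (multivariate
  hypergeometric).  Each sample's stream is keyed by (global seed,
  CRC-32 of the sample id), so results do not depend on sample order.
* *PCoA* is classical scaling: double-center −½ J D² J, eigendecompose,
  scale eigenvectors by √λ.  Negative eigenvalues are reported but
  excluded from coordinates; eigenvalues below 1e-10 of the spectral
  radius count as zero.

The test suite checks both UniFrac variants against a brute-force
per-edge enumeration oracle (independent tree library, explicit set
arithmetic) to 1e-12 on 1000 random instances, and against scikit-bio.

## Dyadic inference

Dyad categories pair hosts by role: all household members; couples
(adult_M × adult_F); father/mother × child (3–18 y, the age bounds are
parameters) or × infant (0–1 y); cohabiting dogs; owner × own dog vs
owner × other dogs.  For each category at one body site, the *pair
universe* is every role-compatible cross-household and within-household
pair; within pairs share a household.  The statistic ranks all universe
distances jointly (midranks for ties) and contrasts mean between- and
within-ranks, normalized by N/2 so R ∈ [−1, 1].

The permutation null shuffles household labels among individuals within
each role stratum (fathers among fathers, mothers among mothers, …) and
rebuilds the dyads; because the universe is invariant under relabeling,
ranks are computed once.  This permutes the exchangeable unit — the
individual, not the (non-exchangeable) dyadic distance.  The test is
one-sided (within < between), with the add-one estimator p = (1 + #{R*
≥ R}) / (1 + n_perm), so p ≥ 1/(n_perm+1) and a calibrated test has
exact level on the permutation grid.  Fewer than ~100 distinct
relabelings triggers a warning recorded in the result.  Bonferroni
correction across sites is left to reporting (the taxon-level analyses
apply it internally; the R tables do not).

Calibration: under the null generator the test's type-I error at α =
0.05 sits inside [0.03, 0.07] over 1000 simulated cohorts (the
acceptance suite re-runs this).

*One-way PERMANOVA*: SS_total = (1/N)·Σ_{i<j} d²_ij, SS_within the
group-wise analogue, pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)),
p from 999 label permutations.  SS_within = 0 is flagged as infinite F
with the p-value from permutations alone.  A degenerate but useful
fact: on mutually equidistant points pseudo-F = 1 for any grouping (the
within and between mean squares coincide), which the tests assert.

*Age trajectory*: for each participant with a sample at the site, the
mean distance to all same-site samples of adults aged 30–45 (the
baseline window is a parameter), excluding the participant and — by
default — their own household, so household sharing does not masquerade
as an age effect (`include_own_family=True` restores inclusive
behaviour); then an OLS fit of mean distance on age.  Zero-variance
responses return a flat fit rather than an error.

*Minimal detectable effect*: the two-sample normal-approximation bound
d = (z_{1−α/2} + z_{power})·√(1/n₁ + 1/n₂).  At the shared-phylotype
group sizes n₁ = 2757, n₂ = 3071, α = 0.05, power = 0.90 this gives
d = 0.085.

## Sharing and taxon summaries

Shared phylotypes between two samples = OTUs with ≥ 1 read in both.
Counting assumes a common rarefaction depth; unequal depths warn rather
than error, since the caller may have standardized effort otherwise.
Per-taxonomy-family partitions of the shared count always sum to the
pair's total (a conservation law the tests enforce).  Group contrasts
(within vs between couples; cohabitation × dog-ownership strata) use
two-sided Wilcoxon rank-sum tests — exact enumeration below 25 total
observations, continuity-corrected normal approximation above —
Bonferroni-corrected over families or contrasts.

Family-rank abundance tables are percentages of each sample's total,
with unassigned OTUs pooled as "unclassified".  The age-group ANOVA
retains families whose grand-mean abundance exceeds 1% (a per-group
variant is available, since retention could also be defined per group),
runs a one-way ANOVA over infant/child/adult/senior groups with ≥ 2
samples each, and Bonferroni-corrects over retained families.  Families
with zero variance everywhere are flagged degenerate, not tested.

## Source attribution

A collapsed Gibbs sampler over per-read source labels z_i ∈ sources ∪
{unknown}:

P(z_i = s | ·) ∝ (m_{s,t} + n⁻ⁱ_{s,t} + α_s) / (m_{s,·} + n⁻ⁱ_{s,·} + T·α_s) · (n⁻ⁱ_s + β)

with m the pooled training counts (zero for "unknown", which uses
α_unknown in place of α_s), n the current sink assignments excluding
read i, and T the number of taxa.  Defaults α = 0.001, α_unknown = 0.1,
β = 10 follow the published defaults of this sampler family;
proportions are posterior means of n_s/N over 1000 post-burn-in sweeps
(burn-in 100).  A single chain is run per sink (restarts via seed
lists); the inner loop is numba-compiled.  Training pools exclude the
sink's own household by default (leave-one-out), so a sink can never be
"explained" by its own household's source samples.  Known-mixture
recovery: 50/50 two-source sinks at depth 5000 are recovered within
±0.05; recovery error shrinks with sink depth.

## Problem sizes and open design choices

The test and acceptance workloads use reduced cohorts (4–20 households,
100–150 taxa, depths 3000–5000) chosen to give the Monte-Carlo checks
comfortable margins: 1000 null cohorts for calibration, 20 seeds per
grid point for parameter recovery, 1000 random trees for oracle
equivalence.  Where the analysis conventions were genuinely open, the
choices are: raw (unnormalized) weighted UniFrac as default; dog–dog
dyads are cohabiting dog pairs, with owner–dog comparisons a separate
category; the >1% ANOVA retention rule uses the grand mean; age-
trajectory baselines exclude the participant's household; child dyad
bounds are 3–18 y with infants 0–1 y.  Each is a parameter or flag, not
a hard-coded constant.
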