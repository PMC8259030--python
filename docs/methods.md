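# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open.

## 1. The tri-stable switch circuit (`lactoswitch.circuit`)

The engineered strain carries a lambda-phage-derived regulatory circuit
that toggles between two functionalities: accumulation of
β-galactosidase (β-GAL, lacZ product) for lactose digestion, and
expression of membrane-targeted L-lactate dehydrogenase (L-LDH,
ompA-lldD product) that oxidises lactate to pyruvate and thereby
rescues a fermentation-driven pH drop.

The model is a deterministic protein-level ODE system over six
regulators (cI, cro, cII, cIII, β-GAL, L-LDH).  mRNA is not modelled:
no transcript-level rates are available, and protein-level lumping is
the simplest dynamical structure consistent with the circuit logic.
All promoter responses are Hill functions with a basal leak
`v0 + (v - v0) x^n / (K^n + x^n)` (activation) or the mirrored
repression form:

* **placm** — activated by lactose (mM).
* **patp2** — modelled as repression by proton concentration
  h = 10^(-pH), so activity rises monotonically with pH.  The promoter's
  quantitative pH dose-response is uncharacterised; half-repression is
  placed at pH 6 (K_h = 10^-6 M), between the permissive neutral-colon
  condition (pH ~7) and the acidic mouse colon (pH ~5).
* **pR** — repressed by cI; drives cIII and L-LDH.
* **pRM** — repressed by cro; drives β-GAL.
* **pRE** — activated by cII; drives cro and cII additively with placm
  (both genes sit in the lactose-activated positive feedback loop).

cII is degraded by the host protease FtsH; cIII inhibits FtsH, giving
the effective rate `delta_cII + delta_F K_III^m / (K_III^m + cIII^m)`.

### Default parameters

No published parameter set is available for this circuit, so the
defaults are the package's own design, chosen (and fixed) so that the
three qualitative operating regimes exist and are robust:

| parameter | value | rationale |
|---|---|---|
| placm (v, v0, K, n) | 8, 0.05, 5 mM, 2 | activates well below the tens-of-mM lactose reached by a bolus |
| patp2 (v, v0, K, n) | 20, 0.2, 1e-6 M, 2 | strong cI drive at pH 7, ~2% at pH 5 |
| pR, pRM (v, v0, K, n) | 10, 0.05, 1, 2 | unit repression thresholds; 200-fold dynamic range |
| pRE (v, v0, K, n) | 15, 0.1, 4, 2 | feedback ignites only when cII escapes FtsH |
| degradation (1/h) | cI, cro, cIII: 2; cII: 0.5; β-GAL, L-LDH: 0.5 | fast regulators, slower effectors/enzymes |
| FtsH: delta_F, K_III, m | 5, 1, 2 | uninhibited FtsH turns cII over 11x faster |

With these values the circuit has a unique β-GAL-dominant stable state
at (pH 7, no lactose) (β-GAL/L-LDH ≈ 66), a unique L-LDH-dominant state
at (pH 5, high lactose) (ratio ≈ 74), and an intermediate dual-function
regime while signals are mixed.  Because the wiring is a cascade
(pH → cI → cIII → cII-feedback → cro → β-GAL), the only nonlinear
closure is the scalar cII equation; the tests exploit this to
enumerate fixed points independently of the multi-start root finder.

### Numerics

Integration uses LSODA at rtol 1e-8 / atol 1e-10; an integrator failure
raises rather than returning NaNs, and output is clipped to zero only
below 1e-12.  Stable states: multi-start `scipy.optimize.root` with
log-uniform starts on [1e-3, 1e3] (seeded), residual tolerance 1e-9,
stability from the eigenvalues of a central-difference Jacobian
(relative step 1e-6), deduplication at L∞ 1e-6.

## 2. Lumen chemistry (`lactoswitch.lumen`)

State: lactose L, lactate A, pyruvate P (mM) and biomass B
(OD-equivalents).  pH is derived, not stored:

    pH(A) = pH_ref - eta * A / (kappa + A)

a saturating single-parameter depression map.  Full buffer speciation
is not attempted — the medium composition is not characterised — but
the map is monotone, bounded and invertible, which is exactly what the
scenario harnesses need (initial lactate is inverted from a measured
initial pH).

Fluxes (all Michaelis-Menten in their substrate, scaled by biomass):
β-GAL hydrolysis (removes lactose without producing acid), community
fermentation (produces `y_lac` = 4 lactate per lactose; homolactic
stoichiometry, lactose → 2 hexose → 4 lactate), L-LDH oxidation
(lactate → pyruvate; only the engineered arm has L-LDH), a basal
alkalinization `k_alk * B` standing in for community metabolism and
medium consumption (this is what makes control cultures drift up in
pH), and first-order pyruvate uptake (a pure sink; it does not affect
pH).  Biomass grows logistically with a Gaussian pH penalty.

Acid-removal terms (L-LDH and alkalinization) carry a Michaelis factor
`A / (A + 2 mM)`: removal requires encountering the acid.  This keeps
the lactate pool non-negative without a derivative discontinuity and
lets a weakly-fermenting culture settle at a finite residual lactate
instead of sliding to a hard zero.

Arm semantics: `test` uses the circuit's current β-GAL/L-LDH levels;
`control` has biomass with the native β-GAL baseline `Z_native` only
(the empty-vector strain encodes no L-LDH); `model` and `untreated`
carry no engineered bacteria (community enzymes only, in-vivo setting
only).  `Z_native` defaults to 0.1 a.u. — chromosomal expression well
below even the leak of the plasmid-borne pRM promoter.

Two default environments are shipped.  In vitro (adjusted LB culture):
pH_ref 7, eta 3, kappa 20 mM, slow fermentation (V_ferm 0.2/OD·h),
k_alk 0.56, V_ldh 0.3, growth from OD 2 toward 6.  In vivo (mouse
colon): pH_ref 5 (untreated colon is stable near pH 5), eta 1.2, kappa
30 mM, dense community (B ≈ 10) fermenting fast (V_ferm 2.5/OD·h),
k_alk 2, V_ldh 0.7.  The two V_ldh values differ because matrix,
temperature and cell state differ between a shaken culture and the
colonic lumen; both were fixed once so the simulated directions match
the experimental narrative (test cultures end above controls with the
largest gap in the most acidic set; the gavaged colon troughs within
6 h while the treated colon stays near baseline).  The in-vivo lactose
gavage (12 mg per 20 g body weight) maps to an initial concentration
via a configurable lumen volume, default 0.4 mL → ≈ 87.7 mM.

Scenario presets: `pH_set_I/II/III` (12 h, initial pH 4.54/5.34/6.25,
1% lactose, test+control arms) and `invivo_{untreated,model,control,
test}` (6 h, initial pH 5.0, gavage at t = 0 except untreated).  For
the test arm the regulators start from the circuit rest state of the
pre-exposure condition: neutral pre-culture (pH 7) in vitro, the
colonised colon's pH in vivo.

## 3. Beta-diversity analysis (`lactoswitch.ordination`)

* **Rarefaction** to 4000 reads (default) by multivariate
  hypergeometric draws (`numpy.random.Generator`); samples below depth
  are dropped and logged, never scaled.
* **Profiles**: a pseudocount of 1e-6 is added to the relative
  abundances (not the raw counts — the pseudocount is a property of the
  distribution comparison, not of sequencing) and renormalised.
* **Distance**: D(a,b) = sqrt(JSD(p_a, p_b)) with natural-log KLD, so
  D ∈ [0, sqrt(ln 2) ≈ 0.8326].  The log base is a convention the
  source methods leave open; natural log is used throughout and the
  bound is asserted in tests.  sqrt-JSD is a metric; the suite checks
  symmetry, identity and the triangle inequality on random triples.
* **PCoA**: classical Torgerson scaling (double-centre -D²/2, `eigh`,
  scale eigenvectors by sqrt of the positive eigenvalues).  Negative
  eigenvalues are reported, not corrected.  Axis signs are fixed
  deterministically (largest-magnitude loading positive) so PCo1
  trajectories are reproducible run to run.  Cross-checked against
  scikit-bio's implementation in the tests.
* **Loess**: local quadratic with tricube weights over the `span`
  (default 0.75) fraction of nearest points, per group; 95% pointwise
  band from the linear-smoother variance with the residual variance
  estimated at the observed points.  Degree-2 local fits with bands are
  not available in the installed stack, so the smoother is implemented
  here and checked against exact weighted-least-squares cases.
* **Per-day tests**: two-sided Mann-Whitney per (day, group-pair) cell;
  exact null when both sides have ≤ 8 observations and no cross-group
  ties, mid-rank normal approximation with tie correction otherwise.
  Benjamini-Hochberg is applied jointly across all testable cells of a
  run (cells with < 2 observations per side are excluded from the
  family).

## 4. Network inference (`lactoswitch.network`, `lactoswitch.glasso`)

Features are prevalence-filtered (present in ≥ 20% of samples,
inclusive threshold), CLR-transformed (log pseudocounted proportions,
row-centred), and a sparse inverse covariance is estimated by graphical
lasso along a 20-point log-spaced penalty path from lambda_max (the
largest absolute off-diagonal correlation, the smallest penalty giving
an empty graph) down to lambda_max/100.

**Solver.** The penalized objective (off-diagonal L1 only) is minimised
by proximal gradient with FISTA momentum, adaptive restart, a
backtracking line search that also enforces positive-definiteness, and
warm starts along the path (with automatic bridging of hard penalty
jumps).  Convergence is max |ΔΘ| < 1e-6 relative to the largest
precision entry; exceeding the iteration cap raises with the iteration
count.  Edges are |Θ_ij| > 1e-8.  A proximal solver was chosen over
per-column coordinate descent because its cost is dominated by dense
eigen/inverse operations that vectorise well at p ≈ 50-300, which is
what the StARS subsampling loop needs.  The solver is validated against
brute-force penalized-likelihood optimisation on p ≤ 4 problems and
against scikit-learn's `graphical_lasso` (which is never used in the
analysis path).

**Conditioning.** The path is fit on the sample *correlation* — the
precision support is invariant to diagonal rescaling — and for
rank-deficient panels (n ≤ p, routine for ~10-sample condition subsets)
the correlation is shrunk 5% toward the identity.  Without this the
weak-penalty end of the path is unattainable at n = 10, p > 100.

**StARS.** `rep_num` (default 50) subsamples without replacement of
size b(n) = min(⌊10√n⌋, ⌊0.8 n⌋); per-penalty edge instability is the
mean over node pairs of 2ξ(1-ξ) with ξ the subsample edge frequency
(maximum 0.5 at ξ = 0.5).  The running supremum along decreasing
penalty is monotonised and the *densest* penalty with supremum ≤ β
(default 0.05) is selected; the model is refit on the full data at that
penalty.  If no penalty qualifies the densest path end is returned with
`stars_converged_ = False`.

**Condition subsets** follow the study design: "normal condition" =
untreated days 7+11; "lactose feeding" = model/control days 5, 7, 11
plus test days 5, 7; "treatment" = test days 11+13.  Selectors must not
overlap.  Default mode fits one network per subset from that subset's
own samples on the shared prevalence-filtered node set; a pooled mode
(one network, per-subset node abundances) is available, since the
source design is ambiguous between the two.  Node sizes are per-subset
mean relative abundances; the top-50 nodes by overall mean abundance
are flagged.  Per-taxon contrasts sum the relative abundances of all
features with a matching genus label (any confidence; mean confidence
reported) and compare subsets by two-sided Mann-Whitney.

## 5. Synthetic data (`lactoswitch.synth`)

`simulate_study` emulates the 21-day, 4-group murine design: 10 mice
per group, phases I-IV of 3/6/6/6 days, sampling every second day with
a rotating half of the mice per day (11 days × 5 mice = 55 samples per
group, matching the reported 53-59).  Ground truth, on the latent log
scale:

* log-normal baseline across 300 features (sd 1.5); 35 of the top-50
  features are labelled class Bacteroidia / genus Bacteroides (several
  as *Bacteroides acidifaciens*), one top feature is a
  *Lactobacillus murinus*-like taxon;
* per-mouse heterogeneity (sd 0.3); cage random intercepts exist but
  default to 0;
* a shared drift of the Bacteroidia block, ramping linearly over days
  3-11 to 0.8 log units in every group — a stand-in for the unexplained
  drift of healthy communities, not a mechanism claim;
* the lactose effect: -0.5 log on the Bacteroides block and +0.7 log on
  the Lactobacillus taxon, applied to model/control/test in phase II
  and to model/control in phase III; the treated (test) group reverts
  to the baseline trend in phase III;
* counts: Dirichlet-multinomial with concentration 200 at log-normal
  depths (mean 8000, sigma 0.35, so a small tail falls below the 4000
  rarefaction depth and exercises sample dropping).  The
  Dirichlet-multinomial was chosen over a log-normal-multinomial for
  its closed-form expectations.

`null_study` zeroes the drift and both effects, making groups
exchangeable by construction; it calibrates the per-cell type-I rate of
the Mann-Whitney stage.  The calibration replicates are scaled down
(2 groups × 8 mice × 3 days, 60 features, depth ~1200 rarefied to 500):
8-vs-8 cells use the exact Mann-Whitney null, whose attained two-sided
level at 0.05 is 0.0499 — essentially nominal, so the binomial-interval
check is meaningful.  (Smaller cells would make the exact test
conservative: at 5-vs-5 the attained level is 0.032.)

`simulate_precision_graph_data` draws Gaussian data from chain/banded/
random sparse precision matrices rescaled to strict diagonal dominance;
the recovery benchmark (p = 50, n = 200, banded, StARS with rep_num 20)
scores F1 ≈ 0.85 against the known support.

What the generator does **not** emulate: real taxonomic correlation
structure (features are conditionally independent given the Dirichlet
mean), sequencing error and chimeras, compositional interactions
between the effect and the rest of the community, cage and litter
effects (off by default), and the actual magnitude of murine temporal
variability.  Passing tests therefore demonstrate that the pipeline
recovers effects of the modelled kind at realistic sample sizes — not
that the biological effect sizes are as reported.

## 6. Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; CLI runs write a
manifest (command, config hash, seed, package version) and all tabular
output is tab-separated text at 9 significant digits, so identical
inputs reproduce byte-identical outputs.  The shipped test and
acceptance workloads use deliberately compact problem sizes — 500
scaled null replicates, 50 pattern seeds, 5 recovery seeds at p = 50,
n = 200 — chosen as the smallest designs at which the checked
properties are statistically meaningful.  The default pipeline demo
caps the network stage at the 60 most abundant features; the library
functions themselves have no such cap.

## 7. Known limitations

* Circuit parameters are designed, not fitted; only directional and
  regime-level conclusions should be drawn from the simulations.
* The pH map collapses all buffering into two constants; absolute pH
  excursions are stylised even where their ordering is meaningful.
* The in-vivo environment treats the colon as a well-mixed batch
  reactor over 6 h (no absorption, transit or secretion).
* Loess bands assume homoscedastic residuals within a group.
* StARS instability is estimated from `rep_num` subsamples; with very
  few samples (n ≈ 10) the subsample pool is tiny and selection is
  coarse.
* glasso edge signs/weights are not interpreted; only the support is
  reported, as in the unweighted source analysis.
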