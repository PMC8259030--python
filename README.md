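# lactoswitch

Modelling and analysis toolkit for an engineered-probiotic approach to
lactose intolerance, and for the microbiome time-series experiments used
to evaluate it — exercised entirely on synthetic data.

When unabsorbed lactose reaches the colon it is fermented to lactic
acid, dropping the luminal pH and disturbing the resident community.
An engineered *E. coli* strain carries a lambda-phage-derived
**tri-stable switch** that toggles between two jobs in response to the
lactose and pH signals: accumulate β-galactosidase (β-GAL, digest the
lactose) when the colon is near neutral, and express L-lactate
dehydrogenase (L-LDH, oxidise lactate to pyruvate and rescue the pH)
when fermentation acidifies the lumen.  This package provides:

* **`lactoswitch.circuit`** — a protein-level ODE model of the switch
  (cI, cro, cII, cIII, β-GAL, L-LDH; Hill promoter kinetics, FtsH-
  mediated cII degradation inhibited by cIII), with trajectory
  integration and seeded multi-start stable-state enumeration.
* **`lactoswitch.lumen`** — the coupled lumen chemistry (lactose,
  lactate, pyruvate, biomass; pH derived from lactate by a saturating
  depression map), plus scenario presets reproducing a 12-h in-vitro
  culture at three pH set points and a 6-h in-vivo lactose-gavage
  experiment with untreated/model/control/test arms.
* **`lactoswitch.ordination`** — the beta-diversity pipeline:
  rarefaction (multivariate hypergeometric), pseudocounted profiles,
  the sqrt-Jensen-Shannon-divergence metric
  D(a,b) = √(½KLD(p_a,m) + ½KLD(p_b,m)), m = (p_a+p_b)/2,
  classical PCoA, per-group loess trajectories of PCo1 with 95% bands,
  and per-day Mann-Whitney tests with Benjamini-Hochberg correction.
* **`lactoswitch.network`** / **`lactoswitch.glasso`** — SPIEC-EASI-
  style condition networks: ≥20% prevalence filter, CLR transform, an
  L1-penalized sparse inverse covariance solver (proximal gradient with
  warm-started penalty paths), StARS stability selection
  (nlambda=20, lambda.min.ratio=0.01, rep.num=50 defaults), per-subset
  node abundances for the top-50 ASVs, and per-genus abundance
  contrasts.
* **`lactoswitch.synth`** — generators for a 4-group × 21-day ASV count
  study with a known lactose-suppression/treatment-recovery effect
  (Dirichlet-multinomial counts), matched null studies, and Gaussian
  draws from known sparse precision graphs for network-recovery
  scoring.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate the 6-h in-vivo experiment and compare arms:

```python
from lactoswitch.lumen import preset_scenarios, run_scenario, compare_arms

trajs = [run_scenario(preset_scenarios(f"invivo_{a}")[0])
         for a in ("untreated", "model", "test")]
print(compare_arms(trajs)["troughs"].round(3).to_string(index=False))
```

```
      arm  trough_time_h  trough_pH  trough_depth  max_abs_deviation
untreated           0.00      5.000         0.000              0.000
    model           5.25      3.950         1.050              1.050
     test           0.75      4.677         0.323              0.323
```

The untreated colon holds pH 5.000; the lactose-gavaged (model) colon
acidifies by 1.05 pH units with its trough inside the 6-h window; the
colon colonised by the engineered strain (test) never deviates more
than 0.32 units — the circuit switches to L-LDH and clears the lactate.

Run the microbiome pipeline on a synthetic study:

```python
from lactoswitch.synth import StudyConfig, simulate_study
from lactoswitch.ordination import (rarefy, to_relative, pairwise_jsd,
                                    PCoA, per_day_group_tests)

table = rarefy(simulate_study(StudyConfig(seed=0)), depth=4000, seed=0)
D = pairwise_jsd(to_relative(table, pseudocount=1e-6))
ordn = PCoA(n_components=2).fit(D)
tests = per_day_group_tests(ordn.coordinates_[:, 0], table.metadata,
                            [("test", "model")])
print(tests[tests.day.isin([9, 11, 13, 15])].round(4).to_string(index=False))
```

```
 day group_a group_b  n_a  n_b   U      p      q
   9    test   model    5    4 9.0 0.9048 1.0000
  11    test   model    5    5 0.0 0.0079 0.0291
  13    test   model    5    5 0.0 0.0079 0.0291
  15    test   model    5    5 0.0 0.0079 0.0291
```

While both groups receive lactose (day 9) their communities are
indistinguishable on PCo1; once the test group is treated (days 11-15)
it separates from the model group at q < 0.05 — the treated community
resumes the normal drift that lactose had been suppressing.

A command-line interface wraps the same stages
(`lactoswitch synth|simulate-circuit|simulate-scenario|beta-diversity|
ordinate|trajectory|group-test|network|run`, each with `--seed`,
`--config` and `--out`); every run writes a manifest with the seed and
config hash, and reruns are byte-identical.

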