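# protailor

Tools for condensing the NCI PRO-CTCAE symptomatic adverse-event library
into a tailored core survey for phase I oncology trials.

## The problem

Phase I oncology trials need patient-reported outcomes (PROs) to assess
*tolerability* — how acceptable a drug's adverse effects are from the
patient's perspective — but the full PRO-CTCAE item library (124 survey
items covering 80 terms) is too long for routine phase I use. A tailored
survey is built by scoring every term on pooled patient responses and
eliminating terms in a fixed sequence of steps:

1. **Prevalence** — the fraction of administered surveys in which any
   attribute of a term was above its null level; terms below 5% are
   eliminated.
2. **Severity proportion score** — among symptomatic responses, the
   fraction with severity ≥ "moderate"; terms below 25% are eliminated.
   Terms without a severity question are carried forward unjudged.
3. **Interference**, 4. **frequency**, 5. **amount** proportion scores —
   same 25% rule and carry-forward logic, cut at ≥ "somewhat" /
   "occasionally" / "somewhat".
6. **Domain reliability** — per organ-system domain, Cronbach's alpha
   `α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ)` is computed on per-term composite
   scores, then recomputed leaving each term out (`Δα = α₂ − α₁`,
   percent change `Δα/α₁`). The term whose removal changes domain
   reliability least is removed — one per domain with more than two
   remaining terms.
7. **Physician impact** — an expert panel rates each surviving term's
   impact on tolerability; terms with fewer than 25% of ratings at
   ≥ "moderate" are removed, and panel-nominated terms eliminated
   earlier may be reintroduced.

Every decision is recorded in an auditable elimination ledger with a
conservation invariant (library size − eliminated + reintroduced =
final size). Because the original cohort's item-level responses are not
public, the package also ships a latent-factor ordinal survey simulator
whose marginals are exact by construction, so the whole pipeline can be
exercised and validated end to end.

## Worked example

```python
import protailor as pt
from protailor import study
from protailor.synthetic_data import (
    study_like_fixture, simulate_survey_data, simulate_physician_panel)

fx = study_like_fixture(n_patients=1000, seed=1)
dataset = simulate_survey_data(fx.config, fx.library, seed=3)
panel = simulate_physician_panel(fx.panel_config, fx.library.term_ids, seed=4)

config = pt.TailoringConfig(reintroduction_terms=study.REINTRODUCED)
ledger, survey, report, scores, rel = pt.run_pipeline(
    dataset, panel, fx.library, config)
print(ledger.survivor_counts())
print(len(survey.terms), survey.max_item_count, survey.domain_count)
```

prints

```
{'prevalence': 62, 'severity': 50, 'interference': 45, 'frequency': 45,
 'amount': 44, 'reliability': 37, 'impact': 30}
30 58 11
```

i.e. the seven steps take the 80-term library to 62 → 50 → 45 → 45 →
44 → 37 survivors from patient data and to a final 30-term survey after
the physician step; the final survey carries at most 58 items across 11
organ-system domains — the development study's published trajectory,
reproduced here from simulated data alone.

The same pipeline is available from the shell:

```bash
protailor simulate --seed 1 --n-patients 1000 --out sim/
protailor score  --responses sim/responses.csv --out scores.csv
protailor tailor --responses sim/responses.csv --panel sim/panel.csv --out run/
```

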