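# hboc-triage

A triage engine for population-based hereditary breast/ovarian cancer
(HBOC) screening, modelled on the multistep programme run in
Emilia-Romagna (Italy): a primary family-history questionnaire scored at
the mammography screening visit, a second-tier risk assessment at local
**Spoke** centres, and genetic counselling with *BRCA1/2* testing at
regional **Hub** centres. The package is for epidemiologists and
screening-programme engineers who want to score family histories, apply
referral and testing criteria reproducibly, generate surveillance
schedules, and account for the attrition funnel of a multistep programme
— on real records or on simulated populations.

## What it implements

**Questionnaire grid.** Each breast (BC) or ovarian (OC) cancer in the
family contributes 0–2 points depending on the relative's kinship row and
an age-at-onset band (&lt;40; 40–49 split bilateral/monolateral; 50–59;
≥60; a single OC column). Male breast cancer scores 2 at any age and any
kinship. A woman with total score ≥ 2 is referred to a Spoke centre, as is
any woman with her own BC diagnosed at 36–40 years.

**Direct Hub criteria.** Seven family-history features bypass the Spoke
tier entirely and also define *BRCA1/2* test eligibility: male BC; BC and
OC in the same patient or family; early-onset BC (≤35); bilateral BC ≤50;
non-mucinous non-borderline OC; two first-degree-related BC cases with one
≤40 or bilateral; triple-negative BC ≤60.

**Risk profiles.** Women at the Spoke are stratified by the ratio of
lifetime BC risk to the population lifetime risk, as produced by an
external calculator (the programme used Tyrer-Cuzick; this package models
only the calculator's *output* contract and accepts injected ratios):
profile 1 (low, ratio &lt; 2), profile 2 (intermediate, 2 ≤ ratio ≤ 3),
profile 3 (high, ratio &gt; 3 → Hub referral).

**Surveillance.** Per-profile schedules (ultrasound, mammography, MRI,
transvaginal ultrasound + Ca.125), including the intensified protocol for
proven carriers and the post-mastectomy / prior-OC modifiers.

**Funnel accounting.** Stage counts with exact one-decimal percentages
(half-up rounding), stratified tables by age band and referral source, and
a simulator that generates whole screening populations under an
autosomal-dominant carrier/penetrance model so the entire pipeline can be
exercised end to end.

## Worked example

```python
from hboc_triage import (CancerDiagnosis, Individual, Pedigree,
                         total_score, route, assess, build_plan)

ped = Pedigree(
    proband_id="P",
    individuals={
        "P": Individual(id="P", sex="female", age=46, mother_id="M", father_id="F"),
        "M": Individual(id="M", sex="female", age=74, alive="yes",
                        diagnoses=[CancerDiagnosis(site="breast", age_at_onset=38)]),
        "F": Individual(id="F", sex="male", age=77),
    },
)
gs = total_score(ped)
print(gs.total, gs.spoke_eligible)      # 2 True   (mother, BC <40 -> 2 points)
dec = route(ped, gs)
print(dec.route.value, dec.reasons)     # spoke ['GRID_GE2']
ra = assess(ped, lifetime_risk_ratio=3.4)   # e.g. an external Tyrer-Cuzick run
print(ra.profile, ra.hub_referable)     # 3 True
plan = build_plan(ra.profile, carrier=False, current_age=46)
print(plan.items[0])                    # ScheduleItem(modality=<Modality.US: 'US'>,
                                        #   start_age=25, end_age=60, interval_months=6, ...)
```

The mother's breast cancer at 38 scores 2 points, which meets the Spoke
threshold but satisfies no direct criterion; a high external risk ratio
then makes the woman Hub-referable, and her profile-3 plan starts with
six-monthly ultrasound from 25 to 60.

The same flows are scriptable from the shell:

```sh
hboc-triage simulate --n 100 --seed 7 --out pop.json   # synthetic population
hboc-triage score family.json                          # grid contributions + total
hboc-triage triage family.json                         # route + criteria + index case
hboc-triage plan --profile 3 --carrier --age 30        # surveillance schedule
hboc-triage report --published                         # published funnel, recomputed %
```

## Layout

- `pedigree_io` — family-history data model, kinship inference, JSON/CSV round-trip
- `grid_score` — the questionnaire grid and the score ≥ 2 threshold
- `referral_rules` — direct criteria, routing, test eligibility, index-case choice, variant-class routing
- `risk_profile` — profile bands behind a pluggable risk-model contract (+ a documented toy model)
- `surveillance` — schedule generation and appointment counting
- `funnel` — pipeline orchestration, stage counts, exact percentages, stratified tables
- `synthpop` — synthetic screening populations with Mendelian transmission

See `docs/methods.md` for modelling assumptions and design choices.
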