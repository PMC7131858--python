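# Methods

This note records the models, conventions and design choices behind
`hboc-triage`, in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The screening model

The engine reproduces a three-tier triage workflow for hereditary
breast/ovarian cancer (HBOC) risk in a mammography-screening population:

1. **Primary questionnaire** (at the screening visit, or via a GP or
   specialist): a grid assigns 0–2 points per cancer in the family; total
   ≥ 2 → Spoke referral. Seven *direct criteria* (male BC; BC+OC in the
   same patient or family; BC ≤35; bilateral BC ≤50; non-mucinous
   non-borderline OC; two first-degree-related BC with one ≤40 or
   bilateral; triple-negative BC ≤60) send the woman straight to a Hub.
   A woman whose own BC was diagnosed at 36–40 is Spoke-referred even
   when the grid total is below threshold.
2. **Spoke**: lifetime-risk estimation by an external calculator; the
   ratio to the population lifetime risk assigns profile 1/2/3; profile 3
   → Hub referral.
3. **Hub**: test eligibility is the same seven-feature set; the *index
   case* — the most indicative alive affected family member — is tested
   for *BRCA1/2*; ENIGMA classes C4/C5 are positive (carrier
   surveillance), C1–C3 fall back to profile-based surveillance.

## Conventions the source protocol leaves open

These were genuinely open design points; each is implemented once and
documented here rather than made configurable by stealth:

- **Age 60 in the grid.** The printed band headers (50–59, >60) leave age
  exactly 60 unassigned; it is scored in the last (≥60) band. The
  triple-negative ≤60 direct criterion is evaluated independently, so no
  referral is lost to this choice.
- **Bilateral disease** is one diagnosis, one contribution. Laterality
  splits only the 40–49 band; a bilateral cancer at <40 or ≥50 scores
  under its age column. (Bilateral ≤50 is separately a direct criterion,
  and both can trigger at once.)
- **Unknowns are conservative**: a breast cancer of unknown onset age
  contributes 0 grid points (with a warning) and satisfies no
  age-thresholded criterion; unknown laterality in 40–49 scores as
  monolateral; unknown ovarian histology does not satisfy the
  non-mucinous non-borderline criterion.
- **Kinship labels**: "sister" (and "aunt") require only one shared
  parent, since the questionnaire does not distinguish half-relatives;
  the niece row covers daughters of any sibling; granddaughters and all
  maternal-line cousins fall in the unscored "other" row. Male relatives
  carry no scored row — male BC has its own row worth 2 at any age,
  applied regardless of kinship.
- **First-degree pairs** (for the two-BC criterion) are parent–child or
  *full*-sibling pairs — the genetic meaning of first degree — while the
  proband herself may be one of the two affected.
- **Blood relatives only**: every criterion is evaluated over individuals
  sharing an ancestor (or line of descent) with the proband; a partner
  present only as a link node never contributes.
- **Profile bands**: the low/intermediate boundary is set at ratio 2 on
  the ratio scale — bands [0,2), [2,3], (3,∞). The protocol's verbal
  banding leaves (1×,2×) unassigned; assigning it to profile 1 is this
  package's convention and can be overridden via
  `classify_profile(..., intermediate_min=...)`.
- **Early-onset threshold**: the Hub eligibility list and the direct
  criteria are implemented as one predicate set with the printed
  thresholds (≤35 early onset, ≤50 bilateral, ≤60 TNBC), since the
  eligibility list restates the same features without numbers.
- **Index-case ranking** beyond "alive and affected" is a documented
  heuristic: both sites > non-mucinous non-borderline OC > earliest BC
  onset > bilateral BC > proband first. The original programme's exact
  ranking is not published; callers can bypass `select_index_case`.
- **Profile-3 ultrasound window**: the protocol table's 25–60 range is
  used where the narrative text says "until 49"; the table is the more
  specific source.
- **Carrier ultrasound** starts at max(18, age at mutation detection) and
  ovarian surveillance (six-monthly TVUS + Ca.125) from max(30, detection
  age) to 74; the 30-year floor is this package's choice, standing in for
  "when too young for risk-reducing surgery".
- **MRI for non-carriers at profile 2/3** is emitted as an opaque
  `MRI_PER_EUSOMA` marker: the external guideline's age/interval logic is
  not reproduced, and marker items are excluded from appointment counts.

## Funnel accounting

Percentages are computed with exact decimal arithmetic and rounded
**half-up at one decimal** — the convention that reproduces every
recomputable percentage in the published five-year report of the
Emilia-Romagna programme (shipped as package data in
`data/reported_counts.json`; those counts are *inputs* for reporting and
test fixtures, never outputs of this package). One printed aggregate in
that report (3.5% for 22 289/660 040 = 3.38%) does not reproduce under
any standard rounding and is excluded from machine checks, as is the
abstract's 42.8% variant of the 2342/5554 = 42.2% test rate.

Non-attendance between stages is modelled as independent Bernoulli draws
per step (`PipelineParams`), because the source programme reports
attendance only as observed fractions. With all acceptance probabilities
at 1 the pipeline is deterministic.

## Synthetic populations

`synthpop` generates three-generation families around a screened proband
(aged 45–74 by default): parents and four grandparents always; sisters,
daughters, aunts, a paternal uncle/cousin and a niece by template
presence probabilities. A dominant susceptibility allele is seeded in
founders at carrier frequency 0.004 and transmitted with probability 1/2;
cancer onsets are drawn from per-decade onset probabilities per genotype
(carrier lifetime BC risk ≈ 65%, OC ≈ 20%; non-carrier ≈ 9% and ≈ 1%),
males at 2% of the female BC curve. Tumour features are Bernoulli flags
(bilateral 0.12, triple-negative 0.15, mucinous/borderline 0.10 each).
Referral sources are age-dependent, with the screening programme never
referring women under 45 (its coverage starts at 45).

The defaults were fixed once so that a few percent of probands (measured
≈ 4% at n = 4000, seed 7) are Spoke-eligible — the order of magnitude of
a real screening population — and are not calibrated to any published
cohort. What the simulator deliberately does **not** emulate: regional
demography, secular changes in family size, ascertainment of family
history (recall error is absent — reported histories are exact), multiple
primary tumours per site, and non-BRCA familial clustering. Passing
simulation tests therefore demonstrates internal consistency of the
triage logic and the qualitative carrier-enrichment mechanism, not
predictive performance on real families.

## Numerical and testing notes

- Appointment counting uses rational arithmetic (`fractions.Fraction`) so
  six-monthly grids never drift; events run from an item's start age in
  steps of its interval while not exceeding its end age, counted in
  half-open windows.
- Scoring and routing are order-independent: contributions are sorted by
  (individual id, diagnosis index), and criterion evidence by id.
- The test suite checks the implementation against independent oracles:
  a re-typed copy of the grid, per-criterion predicates coded directly
  over diagnosis lists, Fraction-based percentage rounding, and Fisher's
  exact test for the no-enrichment null. Property suites run at n = 1000
  pedigrees (scoring/criteria), n = 2000 records (funnel conservation,
  enrichment) and n = 4000 families (Mendelian transmission, giving
  >10 000 informative offspring) — sizes chosen to keep the default test
  run fast while leaving binomial tolerances tight.

## Known limitations

- The engine validates but does not impute: missing ages or histology
  reduce sensitivity exactly as they would on paper forms.
- The toy risk model is a labelled stand-in exercising the risk-model
  contract; its relative-risk table is conventional, not fitted, and it
  must not be used for clinical risk estimation.
- Variant classification, laboratory assays, and the periodic C3
  reclassification service are out of scope; variant classes are inputs.
- Absolute cohort sizes and the carrier-yield percentage of any real
  programme are not simulation targets: they depend on population
  parameters (true carrier frequency, family-size distribution,
  attendance behaviour) that the simulator does not claim to know.
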