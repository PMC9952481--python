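# fphss

Multi-expert, multi-attribute decision support under uncertainty, built on
**fuzzy parameterised complex intuitionistic fuzzy hypersoft sets**
(FPCIFHSS), with a Pythagorean-means scoring pipeline that matches patients
to disease-type alternatives via susceptibility sub-intervals of [0, 1].

The motivating application is triage-level susceptibility analysis of brain
tumours in resource-limited settings: a committee of experts (neurologists,
a neuropathologist) appraises a shortlist of tumour types against
combinations of location-based symptoms, and patients — each assigned a
susceptibility sub-interval of [0, 1] — are matched to the tumour types
whose scores fall inside their interval. The library is generic: any
problem with alternatives, disjoint sub-attribute sets and interval-coded
targets fits.

## The model

An expert's opinion about alternative $a$ under a multi-argument tuple of
sub-parameters is a **complex intuitionistic fuzzy number** (CIFN)

$$\langle A_T e^{jB_T},\; A_F e^{jB_F} \rangle,\qquad
A_T + A_F \le 1,\quad A, B/2\pi \in [0,1],$$

where amplitudes carry the magnitude of the truth/falsity grades and phases
carry periodic context. Phases are stored as fractions of $2\pi$
throughout. Attribute tuples are elements of the Cartesian product
$\Im = \prod_i \Xi_i$ of pairwise-disjoint sub-parameter sets.

The scoring pipeline (per decision maker $l$, tuple $\wp$, alternative $a$):

1. **Fuzzy parameterisation** — each tuple's confidence grade is
   $\psi(\wp) = \tfrac12\left[\tfrac{\max_i A_T + \min_i A_F}{2} +
   \tfrac{\max_i B_T/2\pi + \min_i B_F/2\pi}{2}\right]$.
2. **Collapse** — each CIFN becomes a CFN
   $\left(\tfrac{|A_T - A_F|}{2},\, \tfrac{B_T + B_F}{4\pi}\right)$ and then
   a scalar fuzzy value $\tfrac{|\varpi_1 - \varpi_2|}{2} \in [0, 0.5]$.
3. **Weighting and aggregation** — each row is multiplied by its $\psi$;
   the per-expert matrices are summed element-wise into the **core matrix**.
4. **Scoring and matching** — an alternative's score
   $\partial(a)$ is the arithmetic, geometric or harmonic mean (or the
   median) of its core-matrix column; patient $p$ matches $a$ iff
   $\partial(a)$ lies in $p$'s half-open sub-interval (upper bound 1 is
   inclusive).

Union and intersection of two FPCIFHSS structures are also provided
(component-wise max/min aggregation; see `docs/methods.md` for the
deliberate asymmetry in the union's falsity phase).

## Worked example

```python
from fphss import brain_tumour_study, run_pmbsa

result = run_pmbsa(brain_tumour_study())
print(result.core.frame.round(4))
for method, report in result.reports.items():
    print(method, {a: round(s, 4) for a, s in report.scores.items()})
print(result.reports["arithmetic"].matches)
```

prints (abridged; full run in `examples/susceptibility_pipeline.py`):

```
        craniopharyngioma  brain-metastases  medulloblastomas
tuple1             0.1806            0.2871            0.3404
tuple2             0.1994            0.3069            0.3607
tuple3             0.2284            0.3369            0.3912
tuple4             0.2151            0.2633            0.3368
arithmetic {'craniopharyngioma': 0.2059, 'brain-metastases': 0.2985, 'medulloblastomas': 0.3572}
geometric  {'craniopharyngioma': 0.2051, 'brain-metastases': 0.2973, 'medulloblastomas': 0.3566}
harmonic   {'craniopharyngioma': 0.2043, 'brain-metastases': 0.2961, 'medulloblastomas': 0.356}
median     {'craniopharyngioma': 0.2073, 'brain-metastases': 0.297,  'medulloblastomas': 0.3505}
P1: craniopharyngioma, brain-metastases        P4: medulloblastomas
P2: all three                                  P5: medulloblastomas
P3: all three                                  P6: no match (outside scope)
```

Each core-matrix cell is the evidence three experts jointly assign to a
tumour type under one symptom combination; the scores average that evidence
per tumour type, and the match lines read off which patients' susceptibility
intervals contain each score. Patient P6's interval [0.85, 1] contains no
score: P6 is outside the scope of this three-tumour analysis. The ranking
(medulloblastomas > brain-metastases > craniopharyngioma) is identical under
all four statistics — the Pythagorean-means ordering HM ≤ GM ≤ AM holds
column-wise whenever the core matrix is strictly positive.

Other examples: `examples/set_operations.py` (union/intersection),
`examples/random_study_properties.py` (seeded generator + means ordering),
`examples/study_files.py` (JSON study files and CSV matrix export).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch on the bundled study, the per-stage reference
quantities: two fuzzy-parameterisation grades, one CFN phase component, two
psi-weighted matrix entries and two formula-strict core-matrix cells, and
writes them as JSON keyed `t1`–`t7`. The `--seed` also drives a smoke run
of the random-study generator.
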