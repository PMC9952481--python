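# Methods

This note records the model as implemented, the numerical conventions, the
deliberate design choices where the underlying calculus is ambiguous, and
what the test suite does and does not establish.

## Value types and their constraints

A CIFN holds four components `(at, bt, af, bf)`: truth/falsity amplitudes
and phases, phases stored as fractions of 2π (a stored 0.13 means 2π·0.13
radians). Constructors validate and **reject** rather than clamp; a
permissive mode is intentionally absent because silent clamping would mask
data-entry errors in expert opinions.

Enforced constraints: every component in [0, 1] and `at + af ≤ 1` (with
1e-9 slack for float noise). The classical definition also bounds the
phase sum, `bt + bf ≤ 1`; this is **deliberately not enforced**. The
calculus as used in practice — including the bundled reference study, whose
opinion entries routinely have phase sums up to 1.58, and whose published ψ
grades above 0.5 are only reachable with such sums — admits phase sums up
to 2. Consequences, all documented in docstrings:

* phase hesitancy `1 − bt − bf` may be negative; it is guaranteed in
  [0, 1] only for values that also satisfy the classical bound;
* the CFN phase component `(bt + bf)/2` remains in [0, 1], so every
  downstream formula is unaffected;
* the union rule (below) is closed under the relaxed constraint set.

The two collapse maps are `cifn_to_cfn`, giving `(|at − af|/2,
(bt + bf)/2)`, and `cfn_to_fuzzy`, giving `|w1 − w2|/2 ∈ [0, 0.5]`. Both
are symmetric under swapping the truth/falsity roles of their inputs.

## Fuzzy parameterisation

`fp_value` computes, over a tuple's per-alternative CIFNs,

    psi = 1/2 * [(max at + min af)/2 + (max bt + min bf)/2].

It is applied **per decision maker**: each expert's structure carries its
own ψ row (the only reading that reproduces the reference grades, which
differ across experts). Phase terms enter as fractions of 2π — radians
would push ψ past 1. A study file may override ψ explicitly per tuple;
`parameterise` fills only missing grades unless asked to overwrite.

## Union and intersection

On shared tuples the union takes max for truth amplitude, truth phase and
ψ, min for falsity amplitude — but **max for the falsity phase**, breaking
the expected duality with the amplitude rule. The published definition and
its printed worked output are both consistent with max, so the
implementation follows it as defined and flags the asymmetry here; users
who need the dual behaviour can pre-swap phases. Tuples present in only
one operand are copied verbatim by union; intersection is taken over the
shared tuple set only (the definition leaves one-sided tuples unspecified;
dropping them is the conventional reading). Tuples compare by their entry
sequence, not row position.

## Scoring pipeline

All arithmetic is done at full float precision; rounding (half-up, 4
decimals, via `round_half_up`) happens only in reports and displays, because
the reference tables round half-up (0.00975 → 0.0098). Comparisons against
4-decimal reference tables use absolute tolerance 5e-4.

Weighted matrices are `psi(row) × fuzzy(entry)`; the core matrix is their
element-wise sum over experts, all experts weighted equally (no reliability
weights exist in the underlying method). Scores aggregate each
alternative's core column with one of four statistics. The median is not a
Pythagorean mean but is kept as a robust fourth option; report labels name
the statistic actually computed. Geometric and harmonic means raise on
non-positive entries rather than substituting a value.

Patient intervals are lower-inclusive, upper-exclusive, with an upper bound
of exactly 1 treated as inclusive (so [0.85, 1] can capture a perfect
score). Intervals may overlap; a score may match several patients and a
patient several alternatives, and all matches are reported.

## Known discrepancies in the reference study

The bundled case study reproduces a published worked example whose tables
contain two internal inconsistencies; the implementation is formula-strict
in both cases.

1. **Weighted-matrix slip.** One displayed cell (second expert, second
   tuple, third alternative: 0.3224) omits the final halving of the
   collapse map; the strict value is 0.1612. The displayed core matrix
   inherits the slip (0.5219 where strict recomputation gives 0.3607), and
   through it the displayed scores. Tests cover both routes: the
   aggregation and score stages reproduce the displayed tables when fed the
   displayed inputs, and the end-to-end strict pipeline matches 11 of 12
   core cells.
2. **Matching summary.** The reference summary assigns patients P2 and P3
   only the first two tumour types, yet the third type's score (0.3976
   arithmetic, and likewise under the other three statistics) lies inside
   P2's [0.2, 0.4) and P3's [0.2, 0.6). Strict interval membership — the
   stated rule — therefore adds the third type for P2 and P3. The
   implementation follows the rule; the acceptance test pinned to the
   historical summary is left failing by design. The stability claim (the
   same conclusion under all four statistics) does hold.

## Synthetic-data generator

`generate_study` emulates the *structure* of a multi-expert study, not
medicine: identifiers are synthetic, opinions are sampled, and defaults
mirror the bundled case's shape (3 alternatives, sub-parameter set sizes
(2, 2, 1, 1) → 4 tuples, 3 experts, 6 patients). CIFNs are valid by
construction via conditional-uniform sampling — `at ~ U[0, 1]`,
`af ~ U[0, 1 − at]`, phases likewise — chosen over rejection sampling for a
simpler determinism contract (a fixed seed reproduces the document
byte-for-byte). Patient intervals are ordered pairs of U[0, 1] draws.
A green property test on generated studies therefore establishes algebraic
invariants (validity closure, HM ≤ GM ≤ AM, determinism), not clinical
plausibility; generated opinions have no inter-expert correlation or
symptom structure, unlike real panels.

## Limitations

* The calculus offers no neutral/indeterminate membership channel; experts
  must encode hesitancy implicitly through the amplitude residual.
* Scores depend on the displayed-versus-strict choice at the weighted
  stage only through the single slipped cell; other studies processed with
  this package are always strict.
* Interval matching is a point-in-interval test; no ranking of multiple
  matches or tie-breaking is attempted, mirroring the underlying method.
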