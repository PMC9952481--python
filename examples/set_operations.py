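"""Union and intersection of two fuzzy parameterised hypersoft structures.

Two experts approximate the same two alternatives under the same argument
tuples; the union keeps the most optimistic grades (max truth, min falsity
amplitude) and the intersection the most pessimistic.  Note the published
union rule takes max for the *falsity phase* as well — an asymmetry kept
deliberately (see docs/methods.md).
"""

from fphss import CIFN, FPCIFHSS, FPRow, fphss_intersection, fphss_union

alts = ("alt1", "alt2")
t = ("sub-a", "sub-b")  # one tuple: one sub-parameter per parameter

first = FPCIFHSS(alts, {t: FPRow(0.4, {
    "alt1": CIFN(0.5, 0.3, 0.2, 0.4),
    "alt2": CIFN(0.1, 0.6, 0.7, 0.2),
})})
second = FPCIFHSS(alts, {t: FPRow(0.7, {
    "alt1": CIFN(0.3, 0.5, 0.4, 0.1),
    "alt2": CIFN(0.2, 0.2, 0.6, 0.5),
})})

for name, op in (("union", fphss_union), ("intersection", fphss_intersection)):
    result = op(first, second)
    row = result.rows[t]
    print(f"{name}: psi = {row.psi}")
    for alt, entry in row.approximation.items():
        print(f"  {alt}: {entry}")

# psi follows the same optimism/pessimism: union keeps max(0.4, 0.7) = 0.7,
# intersection min = 0.4; each printed CIFN component is the max/min of the
# two experts' corresponding components.
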