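"""Attribute machinery and the fuzzy parameterised hypersoft container.

A *hypersoft set* evaluates alternatives not against single attributes but
against multi-argument tuples: each parameter (e.g. a symptom family) is
refined into a set of sub-parameters, the sub-parameter sets are pairwise
disjoint, and the evaluation arguments are the elements of their Cartesian
product.  :class:`ParameterSpace` holds the parameters and their sub-sets;
:func:`cartesian_tuples` enumerates the argument tuples.

:class:`FPCIFHSS` is the fuzzy parameterised complex intuitionistic fuzzy
hypersoft set: each argument tuple carries an optional fuzzy parameterised
grade ``psi`` in [0, 1] (confidence in that combination of sub-parameters)
and maps every alternative to a :class:`~fphss.grades.CIFN` approximation.

Union and intersection aggregate two such structures component-wise:

* union: truth amplitude/phase by ``max``, falsity amplitude by ``min`` —
  but falsity *phase* by ``max``, an asymmetry of the published rule that is
  kept as defined (see docs/methods.md); ``psi`` by ``max``;
* intersection: truth by ``min``, falsity by ``max`` (phases both ``min``),
  ``psi`` by ``min``.

Tuples present in only one operand are copied verbatim by the union and
dropped by the intersection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .grades import CIFN

__all__ = [
    "StructureError",
    "ParameterSpace",
    "FPRow",
    "FPCIFHSS",
    "cartesian_tuples",
    "fphss_union",
    "fphss_intersection",
]

SubTuple = tuple[str, ...]


class StructureError(ValueError):
    """A hypersoft structure violates one of its defining constraints."""


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered parameters, each refined into a non-empty disjoint sub-parameter set."""

    parameters: tuple[str, ...]
    sub_sets: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "sub_sets", tuple(tuple(s) for s in self.sub_sets))
        if len(self.parameters) != len(self.sub_sets):
            raise StructureError(
                f"{len(self.parameters)} parameters but {len(self.sub_sets)} sub-parameter sets"
            )
        if len(set(self.parameters)) != len(self.parameters):
            raise StructureError("parameter identifiers must be unique")
        seen: set[str] = set()
        for param, subs in zip(self.parameters, self.sub_sets):
            if not subs:
                raise StructureError(f"parameter {param!r} has no sub-parameters")
            if len(set(subs)) != len(subs):
                raise StructureError(f"duplicate sub-parameter within {param!r}")
            overlap = seen.intersection(subs)
            if overlap:
                raise StructureError(
                    f"sub-parameter sets must be pairwise disjoint; {sorted(overlap)} reused by {param!r}"
                )
            seen.update(subs)

    def validate_tuple(self, entries: SubTuple) -> SubTuple:
        entries = tuple(entries)
        if len(entries) != len(self.parameters):
            raise StructureError(
                f"tuple {entries!r} has {len(entries)} entries, expected {len(self.parameters)}"
            )
        for entry, param, subs in zip(entries, self.parameters, self.sub_sets):
            if entry not in subs:
                raise StructureError(
                    f"entry {entry!r} is not a sub-parameter of {param!r}"
                )
        return entries


def cartesian_tuples(space: ParameterSpace) -> list[SubTuple]:
    """All multi-argument tuples, in lexicographic order of the declared sub-sets."""
    return [tuple(t) for t in itertools.product(*space.sub_sets)]


@dataclass
class FPRow:
    """One argument tuple's row: optional ``psi`` grade plus per-alternative CIFNs."""

    psi: float | None
    approximation: dict[str, CIFN]


@dataclass
class FPCIFHSS:
    """Fuzzy parameterised complex intuitionistic fuzzy hypersoft set.

    ``rows`` maps each sub-parametric tuple to an :class:`FPRow`.  ``psi`` may
    be ``None`` for a structure whose parameterisation has not yet been
    computed (see :func:`fphss.parameterisation.parameterise`).
    """

    alternatives: tuple[str, ...]
    rows: dict[SubTuple, FPRow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alternatives = tuple(self.alternatives)
        if len(set(self.alternatives)) != len(self.alternatives):
            raise StructureError("alternative identifiers must be unique")
        normalised: dict[SubTuple, FPRow] = {}
        for entries, row in self.rows.items():
            entries = tuple(entries)
            if entries in normalised:
                raise StructureError(f"duplicate tuple {entries!r}")
            self._check_row(entries, row)
            normalised[entries] = row
        self.rows = normalised

    def _check_row(self, entries: SubTuple, row: FPRow) -> None:
        if row.psi is not None and not (0.0 <= row.psi <= 1.0):
            raise StructureError(f"psi({entries!r}) = {row.psi!r} is outside [0, 1]")
        got = set(row.approximation)
        want = set(self.alternatives)
        if got != want:
            missing, extra = sorted(want - got), sorted(got - want)
            raise StructureError(
                f"row {entries!r} must approximate exactly the declared alternatives"
                f" (missing {missing}, unexpected {extra})"
            )

    @property
    def tuples(self) -> list[SubTuple]:
        return list(self.rows)

    def psi_of(self, entries: SubTuple) -> float:
        psi = self.rows[tuple(entries)].psi
        if psi is None:
            raise StructureError(f"tuple {tuple(entries)!r} has no fuzzy parameterised grade yet")
        return psi

    def require_psi(self) -> None:
        for entries, row in self.rows.items():
            if row.psi is None:
                raise StructureError(
                    f"tuple {entries!r} has no fuzzy parameterised grade; run parameterise() first"
                )


def _check_same_universe(a: FPCIFHSS, b: FPCIFHSS) -> None:
    if a.alternatives != b.alternatives:
        raise StructureError(
            f"alternative universes differ: {a.alternatives!r} vs {b.alternatives!r}"
        )


def _psi_pair(a: FPCIFHSS, b: FPCIFHSS, entries: SubTuple) -> tuple[float, float]:
    return a.psi_of(entries), b.psi_of(entries)


def fphss_union(a: FPCIFHSS, b: FPCIFHSS) -> FPCIFHSS:
    """Component-wise union of two structures over the same alternatives.

    On shared tuples: truth amplitude and both the truth and falsity phases
    take the max, the falsity amplitude the min, and ``psi`` the max.  Rows
    whose tuple appears in only one operand are copied verbatim.
    """
    _check_same_universe(a, b)
    out: dict[SubTuple, FPRow] = {}
    for entries, row in a.rows.items():
        if entries not in b.rows:
            out[entries] = FPRow(row.psi, dict(row.approximation))
            continue
        other = b.rows[entries]
        psi1, psi2 = _psi_pair(a, b, entries)
        approx = {}
        for alt in a.alternatives:
            x, y = row.approximation[alt], other.approximation[alt]
            approx[alt] = CIFN(
                at=max(x.at, y.at),
                bt=max(x.bt, y.bt),
                af=min(x.af, y.af),
                bf=max(x.bf, y.bf),  # published rule: max, not the dual min
            )
        out[entries] = FPRow(max(psi1, psi2), approx)
    for entries, row in b.rows.items():
        if entries not in a.rows:
            out[entries] = FPRow(row.psi, dict(row.approximation))
    return FPCIFHSS(a.alternatives, out)


def fphss_intersection(a: FPCIFHSS, b: FPCIFHSS) -> FPCIFHSS:
    """Component-wise intersection over the tuples common to both operands."""
    _check_same_universe(a, b)
    out: dict[SubTuple, FPRow] = {}
    for entries, row in a.rows.items():
        if entries not in b.rows:
            continue
        other = b.rows[entries]
        psi1, psi2 = _psi_pair(a, b, entries)
        approx = {}
        for alt in a.alternatives:
            x, y = row.approximation[alt], other.approximation[alt]
            approx[alt] = CIFN(
                at=min(x.at, y.at),
                bt=min(x.bt, y.bt),
                af=max(x.af, y.af),
                bf=min(x.bf, y.bf),
            )
        out[entries] = FPRow(min(psi1, psi2), approx)
    return FPCIFHSS(a.alternatives, out)
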