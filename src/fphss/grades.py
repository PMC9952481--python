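"""Membership-grade value types for intuitionistic and complex fuzzy reasoning.

Three small immutable value types are defined here:

``IFN``
    An intuitionistic fuzzy number: a truth grade ``t`` and a falsity grade
    ``f``, both in [0, 1] with ``t + f <= 1``.  The residual ``1 - t - f`` is
    the hesitancy (indeterminacy) of the judgement.

``CIFN``
    A complex intuitionistic fuzzy number.  Each of the truth and falsity
    grades is a complex value ``A * exp(j*B)``: the amplitude ``A`` carries
    the magnitude of the grade and the phase ``B`` carries periodic context
    (e.g. how a symptom's relevance recurs over time).  Phases are stored as
    *fractions of 2*pi* throughout this package: a stored ``bt = 0.13`` means
    a phase of ``2*pi*0.13`` radians.

``CFN``
    A plain complex fuzzy number, the two-component value produced when a
    CIFN is collapsed by :func:`cifn_to_cfn`.

The two collapse maps are ``cifn_to_cfn`` (CIFN -> CFN) and ``cfn_to_fuzzy``
(CFN -> scalar fuzzy value in [0, 0.5]); together they turn an expert's
complex-valued opinion into a single real number that the scoring pipeline
can weight and aggregate.

A note on validation: amplitudes must satisfy ``at + af <= 1`` and every
component must lie in [0, 1], and constructors *reject* violations rather
than clamping them (silent clamping would mask data-entry errors in expert
opinions).  The classical definition also bounds the phase sum by 2*pi, but
the calculus as applied in practice admits phase sums up to 4*pi, so only
the per-component bound is enforced here; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "IFN",
    "CIFN",
    "CFN",
    "GradeError",
    "hesitancy_ifn",
    "hesitancy_cifn",
    "cifn_to_cfn",
    "cfn_to_fuzzy",
    "round_half_up",
]

#: slack for floating-point noise when validating unit-interval constraints
_EPS = 1e-9


class GradeError(ValueError):
    """A membership grade violates one of its defining constraints."""


def _check_unit(name: str, value: float) -> None:
    if not (-_EPS <= value <= 1.0 + _EPS):
        raise GradeError(f"{name} = {value!r} is outside [0, 1]")


@dataclass(frozen=True)
class IFN:
    """Intuitionistic fuzzy number: truth grade ``t`` and falsity grade ``f``."""

    t: float
    f: float

    def __post_init__(self) -> None:
        _check_unit("truth grade t", self.t)
        _check_unit("falsity grade f", self.f)
        if self.t + self.f > 1.0 + _EPS:
            raise GradeError(
                f"t + f = {self.t + self.f!r} exceeds 1 (t={self.t!r}, f={self.f!r})"
            )

    @property
    def hesitancy(self) -> float:
        """Residual indeterminacy ``1 - t - f``, in [0, 1]."""
        return 1.0 - self.t - self.f


@dataclass(frozen=True)
class CIFN:
    """Complex intuitionistic fuzzy number.

    Parameters
    ----------
    at, bt:
        Amplitude and phase (fraction of 2*pi) of the truth grade.
    af, bf:
        Amplitude and phase (fraction of 2*pi) of the falsity grade.
    """

    at: float
    bt: float
    af: float
    bf: float

    def __post_init__(self) -> None:
        _check_unit("truth amplitude at", self.at)
        _check_unit("truth phase bt", self.bt)
        _check_unit("falsity amplitude af", self.af)
        _check_unit("falsity phase bf", self.bf)
        if self.at + self.af > 1.0 + _EPS:
            raise GradeError(
                f"amplitude sum at + af = {self.at + self.af!r} exceeds 1 "
                f"(at={self.at!r}, af={self.af!r})"
            )

    @property
    def hesitancy(self) -> tuple[float, float]:
        """``(1 - at - af, 1 - bt - bf)``.

        The amplitude hesitancy is always in [0, 1].  The phase hesitancy is
        reported as a fraction of 2*pi and is in [0, 1] only when the value
        also satisfies the classical phase-sum bound ``bt + bf <= 1``; it may
        be negative otherwise (multiply by 2*pi for display in radians).
        """
        return (1.0 - self.at - self.af, 1.0 - self.bt - self.bf)

    def as_array(self) -> list[float]:
        """Serialisation order used by study files: ``[at, bt, af, bf]``."""
        return [self.at, self.bt, self.af, self.bf]

    @classmethod
    def from_array(cls, values) -> "CIFN":
        if len(values) != 4:
            raise GradeError(f"a CIFN needs 4 components [at, bt, af, bf], got {len(values)}")
        return cls(*(float(v) for v in values))

    def __str__(self) -> str:  # renders phases in the conventional 2pi(x) style
        return (
            f"<{self.at:g}e^j2π({self.bt:g}), {self.af:g}e^j2π({self.bf:g})>"
        )


@dataclass(frozen=True)
class CFN:
    """Complex fuzzy number with components ``w1`` (amplitude-derived) and ``w2`` (phase-derived)."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        _check_unit("first component w1", self.w1)
        _check_unit("second component w2", self.w2)


def hesitancy_ifn(x: IFN) -> float:
    """Hesitancy grade ``1 - t - f`` of an intuitionistic fuzzy number."""
    return x.hesitancy


def hesitancy_cifn(x: CIFN) -> tuple[float, float]:
    """Amplitude and phase hesitancy of a CIFN (phase as a fraction of 2*pi)."""
    return x.hesitancy


def cifn_to_cfn(x: CIFN) -> CFN:
    """Collapse a CIFN into a two-component complex fuzzy number.

    The first component is half the absolute amplitude difference,
    ``|at - af| / 2``; the second is the mean phase fraction
    ``(bt + bf) / 2`` (equivalently ``(B_T + B_F) / (4*pi)`` in radians).
    """
    return CFN(abs(x.at - x.af) / 2.0, (x.bt + x.bf) / 2.0)


def cfn_to_fuzzy(x: CFN) -> float:
    """Collapse a CFN to a scalar fuzzy value ``|w1 - w2| / 2``, in [0, 0.5]."""
    return abs(x.w1 - x.w2) / 2.0


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, as decision-matrix tables conventionally do.

    Python's built-in ``round`` is banker's rounding; reference tables in this
    domain round 0.00975 to 0.0098, so reports use this helper instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
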