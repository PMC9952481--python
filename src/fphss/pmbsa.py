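"""Pythagorean-means-based scoring of alternatives and patient matching.

The pipeline turns per-expert hypersoft opinion structures into a single
ranking of alternatives and a patient assignment, in four stages:

1. *Parameterisation* — each expert's structure gets per-tuple ``psi``
   grades (:mod:`fphss.parameterisation`).
2. *Transformation* — every CIFN entry is collapsed to a scalar fuzzy value
   via the CFN map (:func:`fphss.grades.cifn_to_cfn` then
   :func:`fphss.grades.cfn_to_fuzzy`), and each row is multiplied by its
   ``psi``, giving one weighted fuzzy matrix per expert.
3. *Aggregation* — the weighted matrices are summed element-wise into the
   *core matrix* (rows: tuples; columns: alternatives).
4. *Scoring and decision* — each alternative's score is a statistic
   (arithmetic, geometric or harmonic mean, or the median) of its core-matrix
   column, and a patient matches an alternative when the score falls inside
   the patient's susceptibility sub-interval of [0, 1].

Matrices are pandas DataFrames indexed by tuple label (sub-parameters joined
with ``"|"``) with one column per alternative, which makes the intermediate
stages directly inspectable and writable as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean, hmean

from .grades import cfn_to_fuzzy, cifn_to_cfn
from .hypersoft import FPCIFHSS, StructureError, SubTuple
from .parameterisation import parameterise

__all__ = [
    "METHODS",
    "OpinionMatrix",
    "WeightedFuzzyMatrix",
    "CoreMatrix",
    "SusceptibilityProfile",
    "ScoreReport",
    "PipelineResult",
    "tuple_label",
    "cfn_frame",
    "weight_matrix",
    "core_matrix",
    "scores",
    "match_patients",
    "run_pmbsa",
]

#: statistics accepted by :func:`scores`; the first three are the Pythagorean
#: means, the median is kept as a robust fourth option.
METHODS = ("arithmetic", "geometric", "harmonic", "median")


def tuple_label(entries: SubTuple) -> str:
    """Row label used for matrix indices: sub-parameters joined with '|'."""
    return "|".join(entries)


@dataclass
class OpinionMatrix:
    """One decision maker's hypersoft opinion structure in matrix form."""

    decision_maker: str
    structure: FPCIFHSS

    @property
    def tuples(self) -> list[SubTuple]:
        return self.structure.tuples

    @property
    def alternatives(self) -> tuple[str, ...]:
        return self.structure.alternatives


@dataclass
class WeightedFuzzyMatrix:
    """Per-expert fuzzy values, each row already multiplied by its psi grade."""

    decision_maker: str
    frame: pd.DataFrame


@dataclass
class CoreMatrix:
    """Element-wise sum of all experts' weighted fuzzy matrices."""

    frame: pd.DataFrame


@dataclass(frozen=True)
class SusceptibilityProfile:
    """A patient plus the sub-interval of [0, 1] holding their susceptibility degree.

    The interval is lower-inclusive and upper-exclusive, except that an upper
    bound of exactly 1 is inclusive (so [0.85, 1] covers the top score 1.0).
    """

    patient: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(
                f"invalid interval [{self.lower!r}, {self.upper!r}) for patient {self.patient!r}:"
                " need 0 <= lower < upper <= 1"
            )

    def contains(self, value: float) -> bool:
        if self.upper == 1.0:
            return self.lower <= value <= 1.0
        return self.lower <= value < self.upper


@dataclass
class ScoreReport:
    """Scores under one statistic plus the induced patient-alternative matches."""

    method: str
    scores: dict[str, float]
    matches: dict[str, tuple[str, ...]]
    unmatched: tuple[str, ...]


@dataclass
class PipelineResult:
    """All intermediate matrices of one pipeline run, for audit, plus the reports."""

    psi: pd.DataFrame  # rows: decision makers; columns: tuple labels
    cfn: dict[str, pd.DataFrame]  # per expert: CFN components, columns "<alt>|w1", "<alt>|w2"
    weighted: dict[str, WeightedFuzzyMatrix]
    core: CoreMatrix
    reports: dict[str, ScoreReport]


def _fuzzy_value(cifn) -> float:
    return cfn_to_fuzzy(cifn_to_cfn(cifn))


def cfn_frame(matrix: OpinionMatrix) -> pd.DataFrame:
    """CFN components of every entry, columns ``<alt>|w1`` and ``<alt>|w2``."""
    index = [tuple_label(t) for t in matrix.tuples]
    data: dict[str, list[float]] = {}
    for alt in matrix.alternatives:
        pairs = [cifn_to_cfn(matrix.structure.rows[t].approximation[alt]) for t in matrix.tuples]
        data[f"{alt}|w1"] = [p.w1 for p in pairs]
        data[f"{alt}|w2"] = [p.w2 for p in pairs]
    return pd.DataFrame(data, index=index)


def weight_matrix(matrix: OpinionMatrix) -> WeightedFuzzyMatrix:
    """Collapse every CIFN to a fuzzy value and weight each row by its psi grade."""
    matrix.structure.require_psi()
    index = [tuple_label(t) for t in matrix.tuples]
    data = {
        alt: [
            matrix.structure.rows[t].psi * _fuzzy_value(matrix.structure.rows[t].approximation[alt])
            for t in matrix.tuples
        ]
        for alt in matrix.alternatives
    }
    return WeightedFuzzyMatrix(matrix.decision_maker, pd.DataFrame(data, index=index))


def core_matrix(matrices: Sequence[WeightedFuzzyMatrix]) -> CoreMatrix:
    """Element-wise sum of the experts' weighted matrices (all shapes must agree)."""
    if not matrices:
        raise StructureError("need at least one weighted matrix")
    first = matrices[0].frame
    total = first.copy()
    for wm in matrices[1:]:
        frame = wm.frame
        if list(frame.index) != list(first.index):
            extra = set(frame.index).symmetric_difference(first.index)
            raise StructureError(
                f"tuple rows of {wm.decision_maker!r} disagree with {matrices[0].decision_maker!r}:"
                f" {sorted(extra)}"
            )
        if list(frame.columns) != list(first.columns):
            extra = set(frame.columns).symmetric_difference(first.columns)
            raise StructureError(
                f"alternative columns of {wm.decision_maker!r} disagree: {sorted(extra)}"
            )
        total = total + frame
    return CoreMatrix(total)


def scores(core: CoreMatrix, method: str = "arithmetic") -> dict[str, float]:
    """Aggregate each alternative's core-matrix column with the requested statistic.

    Geometric and harmonic means are undefined when an entry is zero (or
    negative); that raises rather than silently substituting a value.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    out: dict[str, float] = {}
    for alt in core.frame.columns:
        column = core.frame[alt].to_numpy(dtype=float)
        if method == "arithmetic":
            out[alt] = float(np.mean(column))
        elif method == "median":
            out[alt] = float(np.median(column))
        else:
            if np.any(column <= 0.0):
                raise ValueError(
                    f"{method} mean undefined for alternative {alt!r}: "
                    "core column contains a non-positive entry"
                )
            out[alt] = float(gmean(column) if method == "geometric" else hmean(column))
    return out


def match_patients(
    score_map: Mapping[str, float],
    profiles: Iterable[SusceptibilityProfile],
    method: str = "arithmetic",
) -> ScoreReport:
    """Match every patient with the alternatives whose score lies in their interval."""
    matches: dict[str, tuple[str, ...]] = {}
    unmatched: list[str] = []
    for profile in profiles:
        hits = tuple(alt for alt, s in score_map.items() if profile.contains(s))
        matches[profile.patient] = hits
        if not hits:
            unmatched.append(profile.patient)
    return ScoreReport(method, dict(score_map), matches, tuple(unmatched))


def run_pmbsa(study, methods: Sequence[str] = METHODS) -> PipelineResult:
    """Run the full scoring pipeline on a study document.

    ``study`` is any object exposing ``opinion_matrices()`` and ``profiles()``
    (see :class:`fphss.study.StudyDocument`).  Each stage's output is kept in
    the returned :class:`PipelineResult` so a run can be audited end to end.
    """
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    opinion_matrices = [
        OpinionMatrix(m.decision_maker, parameterise(m.structure))
        for m in study.opinion_matrices()
    ]
    if not opinion_matrices:
        raise StructureError("study has no decision makers")

    psi = pd.DataFrame(
        {
            tuple_label(t): [m.structure.psi_of(t) for m in opinion_matrices]
            for t in opinion_matrices[0].tuples
        },
        index=[m.decision_maker for m in opinion_matrices],
    )
    cfn = {m.decision_maker: cfn_frame(m) for m in opinion_matrices}
    weighted = {m.decision_maker: weight_matrix(m) for m in opinion_matrices}
    core = core_matrix(list(weighted.values()))

    profiles = list(study.profiles())
    reports = {
        method: match_patients(scores(core, method), profiles, method)
        for method in methods
    }
    return PipelineResult(psi, cfn, weighted, core, reports)
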