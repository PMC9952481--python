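"""Study-file schema and readers/writers.

A *decision study* is a JSON document bundling everything one scoring run
needs: the alternatives, the parameter space (parameters with their disjoint
sub-parameter sets), one opinion block per decision maker (a CIFN for every
sub-parametric tuple x alternative, with an optional explicit ``psi``
override per tuple), and the patients' susceptibility sub-intervals.

CIFNs are serialised as 4-element arrays ``[at, bt, af, bf]``.  Phases are
fractions of 2*pi by default; a study may declare ``"phase_unit":
"radians"`` and will be normalised on load.

Schema validation is pydantic-based, so structural errors carry the JSON
path of the offending field; cross-reference and grade-constraint checks run
afterwards and name the violated constraint.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Sequence

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .grades import CIFN, GradeError
from .hypersoft import FPCIFHSS, FPRow, ParameterSpace, StructureError, cartesian_tuples
from .pmbsa import METHODS, OpinionMatrix, PipelineResult, SusceptibilityProfile

__all__ = [
    "StudyValidationError",
    "ParameterBlock",
    "OpinionRow",
    "ExpertBlock",
    "PatientBlock",
    "StudyDocument",
    "read_study",
    "write_study",
    "write_matrices",
]


class StudyValidationError(ValueError):
    """A study document failed schema, cross-reference or grade validation."""


class ParameterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    sub_parameters: list[str] = Field(min_length=1)


class OpinionRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tuple: list[str]
    psi: float | None = None  # explicit override; computed from the CIFNs when absent
    approximations: dict[str, list[float]]


class ExpertBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    rows: list[OpinionRow] = Field(min_length=1)


class PatientBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    interval: tuple[float, float]


class StudyDocument(BaseModel):
    """Validated decision study; see the module docstring for the layout."""

    model_config = ConfigDict(extra="forbid")

    alternatives: list[str] = Field(min_length=1)
    parameters: list[ParameterBlock] = Field(min_length=1)
    experts: list[ExpertBlock] = Field(min_length=1)
    patients: list[PatientBlock] = Field(default_factory=list)
    phase_unit: Literal["fraction", "radians"] = "fraction"
    methods: list[Literal["arithmetic", "geometric", "harmonic", "median"]] = Field(
        default_factory=lambda: list(METHODS)
    )
    display_digits: int = 4

    @pydantic.model_validator(mode="after")
    def _cross_validate(self) -> "StudyDocument":
        if self.phase_unit == "radians":
            for expert in self.experts:
                for row in expert.rows:
                    for alt, arr in row.approximations.items():
                        if len(arr) == 4:
                            arr[1] /= 2.0 * math.pi
                            arr[3] /= 2.0 * math.pi
            self.phase_unit = "fraction"
        try:
            space = self.parameter_space()
        except StructureError as err:
            raise StudyValidationError(f"parameters: {err}") from err
        expected = set(cartesian_tuples(space))
        alts = set(self.alternatives)
        if len(alts) != len(self.alternatives):
            raise StudyValidationError("alternatives: identifiers must be unique")
        names = [e.name for e in self.experts]
        if len(set(names)) != len(names):
            raise StudyValidationError("experts: decision-maker names must be unique")
        for i, expert in enumerate(self.experts):
            seen: set[tuple[str, ...]] = set()
            for j, row in enumerate(expert.rows):
                where = f"experts/{i}/rows/{j}"
                try:
                    entries = space.validate_tuple(tuple(row.tuple))
                except StructureError as err:
                    raise StudyValidationError(f"{where}/tuple: {err}") from err
                if entries in seen:
                    raise StudyValidationError(f"{where}/tuple: duplicate tuple {entries!r}")
                seen.add(entries)
                if row.psi is not None and not (0.0 <= row.psi <= 1.0):
                    raise StudyValidationError(f"{where}/psi: {row.psi!r} outside [0, 1]")
                if set(row.approximations) != alts:
                    raise StudyValidationError(
                        f"{where}/approximations: must cover exactly the declared alternatives"
                    )
                for alt, arr in row.approximations.items():
                    try:
                        CIFN.from_array(arr)
                    except GradeError as err:
                        raise StudyValidationError(
                            f"{where}/approximations/{alt}: {err}"
                        ) from err
            if seen != expected:
                raise StudyValidationError(
                    f"experts/{i}: rows must cover every sub-parametric tuple exactly once"
                    f" ({len(seen)} given, {len(expected)} expected)"
                )
        pnames = [p.name for p in self.patients]
        if len(set(pnames)) != len(pnames):
            raise StudyValidationError("patients: names must be unique")
        for i, patient in enumerate(self.patients):
            lo, hi = patient.interval
            if not (0.0 <= lo < hi <= 1.0):
                raise StudyValidationError(
                    f"patients/{i}/interval: [{lo!r}, {hi!r}) violates 0 <= lower < upper <= 1"
                )
        return self

    # -- domain-object views -------------------------------------------------

    def parameter_space(self) -> ParameterSpace:
        return ParameterSpace(
            tuple(p.name for p in self.parameters),
            tuple(tuple(p.sub_parameters) for p in self.parameters),
        )

    def opinion_matrices(self) -> list[OpinionMatrix]:
        """Per-expert hypersoft structures, rows in Cartesian-product order."""
        order = cartesian_tuples(self.parameter_space())
        out = []
        for expert in self.experts:
            by_tuple = {tuple(r.tuple): r for r in expert.rows}
            rows = {
                t: FPRow(
                    by_tuple[t].psi,
                    {alt: CIFN.from_array(arr) for alt, arr in by_tuple[t].approximations.items()},
                )
                for t in order
            }
            out.append(OpinionMatrix(expert.name, FPCIFHSS(tuple(self.alternatives), rows)))
        return out

    def profiles(self) -> list[SusceptibilityProfile]:
        return [SusceptibilityProfile(p.name, *p.interval) for p in self.patients]


def read_study(path: str | Path) -> StudyDocument:
    """Load and fully validate a study document from a JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise StudyValidationError(f"{path}: not valid JSON: {err}") from err
    try:
        return StudyDocument.model_validate(raw)
    except pydantic.ValidationError as err:
        locs = "; ".join(
            "/".join(str(part) for part in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise StudyValidationError(f"{path}: schema violation at {locs}") from err


def write_study(study: StudyDocument, path: str | Path) -> Path:
    """Serialise a study document to JSON (stable key order, full precision)."""
    path = Path(path)
    path.write_text(json.dumps(study.model_dump(mode="json"), indent=2, sort_keys=True) + "\n")
    return path


def write_matrices(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write every intermediate matrix of a run as CSV plus a JSON report.

    One CSV per stage and expert (``psi``, ``cfn_<dm>``, ``weighted_<dm>``,
    ``core``), rows labelled by tuple and columns by alternative, plus
    ``report.json`` with full-precision scores and the patient matches.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _dump(frame, name: str) -> None:
        target = out_dir / f"{name}.csv"
        frame.to_csv(target)
        written.append(target)

    _dump(result.psi, "psi")
    for dm, frame in result.cfn.items():
        _dump(frame, f"cfn_{dm}")
    for dm, wm in result.weighted.items():
        _dump(wm.frame, f"weighted_{dm}")
    _dump(result.core.frame, "core")

    report = {
        method: {
            "scores": rep.scores,
            "matches": {p: list(alts) for p, alts in rep.matches.items()},
            "unmatched": list(rep.unmatched),
        }
        for method, rep in result.reports.items()
    }
    target = out_dir / "report.json"
    target.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    written.append(target)
    return written
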