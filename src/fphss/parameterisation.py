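"""Fuzzy parameterisation of sub-parametric tuples.

Each multi-argument tuple gets a confidence grade ``psi`` in [0, 1] computed
from the CIFN approximations it induces over the alternatives:

    psi = 1/2 * [ (max_i at_i + min_i af_i) / 2 + (max_i bt_i + min_i bf_i) / 2 ]

with phases taken as fractions of 2*pi.  The max over truth components and
min over falsity components reads the tuple's best-supported relevance; the
grade is computed per decision maker, so each expert's structure carries its
own parameterisation.
"""

from __future__ import annotations

from typing import Mapping

from .grades import CIFN
from .hypersoft import FPCIFHSS, FPRow

__all__ = ["fp_value", "parameterise"]


def fp_value(approximation: Mapping[str, CIFN]) -> float:
    """Fuzzy parameterised grade of one tuple from its per-alternative CIFNs."""
    if not approximation:
        raise ValueError("cannot parameterise an empty approximation (max/min undefined)")
    values = list(approximation.values())
    amp = (max(v.at for v in values) + min(v.af for v in values)) / 2.0
    pha = (max(v.bt for v in values) + min(v.bf for v in values)) / 2.0
    psi = (amp + pha) / 2.0
    if not (0.0 <= psi <= 1.0):  # cannot occur for valid CIFNs; guards corrupt input
        raise ValueError(f"computed psi = {psi!r} outside [0, 1]")
    return psi


def parameterise(structure: FPCIFHSS, overwrite: bool = False) -> FPCIFHSS:
    """Attach a ``psi`` grade to every tuple of ``structure``.

    Grades already present (e.g. supplied explicitly by an expert) are kept
    unless ``overwrite`` is true.  Returns a new structure; the input is not
    modified.
    """
    rows = {}
    for entries, row in structure.rows.items():
        if row.psi is None or overwrite:
            try:
                psi = fp_value(row.approximation)
            except ValueError as err:
                raise ValueError(f"tuple {entries!r}: {err}") from err
        else:
            psi = row.psi
        rows[entries] = FPRow(psi, dict(row.approximation))
    return FPCIFHSS(structure.alternatives, rows)
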