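"""Seeded generator of random valid decision studies.

The generator emulates the *structure* of a real multi-expert study —
alternatives, disjoint sub-parameter sets, per-expert CIFN opinions,
patient intervals — not any medical content.  Its defaults mirror the
bundled brain-tumour case: 3 alternatives, sub-parameter set sizes
(2, 2, 1, 1) giving 4 tuples, 3 experts and 6 patients.

Validity is guaranteed by construction rather than rejection sampling: the
truth amplitude is drawn uniformly and the falsity amplitude uniformly from
what the constraint ``at + af <= 1`` leaves; phases likewise.  A fixed seed
reproduces the document exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .study import StudyDocument

__all__ = ["GeneratorConfig", "generate_study"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and sampling parameters of a generated study."""

    alternatives: int = 3
    sub_set_sizes: tuple[int, ...] = (2, 2, 1, 1)
    experts: int = 3
    patients: int = 6
    seed: int = 0
    max_amplitude: float = 1.0  # upper bound for sampled amplitudes, in (0, 1]
    max_phase: float = 1.0  # upper bound for sampled phase fractions, in (0, 1]

    def __post_init__(self) -> None:
        if min(self.alternatives, self.experts, self.patients) < 1 or not self.sub_set_sizes:
            raise ValueError("all counts must be >= 1")
        if any(s < 1 for s in self.sub_set_sizes):
            raise ValueError("every parameter needs at least one sub-parameter")
        if not (0.0 < self.max_amplitude <= 1.0 and 0.0 < self.max_phase <= 1.0):
            raise ValueError("sampling ranges must lie within (0, 1]")


def _sample_cifn(rng: np.random.Generator, cfg: GeneratorConfig) -> list[float]:
    at = rng.uniform(0.0, cfg.max_amplitude)
    af = rng.uniform(0.0, min(cfg.max_amplitude, 1.0 - at))
    bt = rng.uniform(0.0, cfg.max_phase)
    bf = rng.uniform(0.0, min(cfg.max_phase, 1.0 - bt))
    return [at, bt, af, bf]


def generate_study(cfg: GeneratorConfig) -> StudyDocument:
    """Generate a random valid study, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    alternatives = [f"alt{i + 1}" for i in range(cfg.alternatives)]
    parameters = [
        {
            "name": f"param{i + 1}",
            "sub_parameters": [f"p{i + 1}s{j + 1}" for j in range(size)],
        }
        for i, size in enumerate(cfg.sub_set_sizes)
    ]
    tuples: list[list[str]] = [[]]
    for block in parameters:
        tuples = [t + [s] for t in tuples for s in block["sub_parameters"]]

    experts = []
    for e in range(cfg.experts):
        rows = [
            {
                "tuple": t,
                "approximations": {alt: _sample_cifn(rng, cfg) for alt in alternatives},
            }
            for t in tuples
        ]
        experts.append({"name": f"Dm{e + 1}", "rows": rows})

    patients = []
    for p in range(cfg.patients):
        lo, hi = np.sort(rng.uniform(0.0, 1.0, size=2))
        while hi <= lo:  # vanishing probability; guards a degenerate draw
            lo, hi = np.sort(rng.uniform(0.0, 1.0, size=2))
        patients.append({"name": f"P{p + 1}", "interval": [float(lo), float(hi)]})

    return StudyDocument.model_validate(
        {
            "alternatives": alternatives,
            "parameters": parameters,
            "experts": experts,
            "patients": patients,
        }
    )
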