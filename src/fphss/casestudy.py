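"""Bundled brain-tumour decision study.

A complete, desk-scale worked case: three candidate tumour types
(craniopharyngioma, brain metastases, medulloblastoma) are appraised by
three decision makers — two neurologists and a neuropathologist — against
four location-based symptom parameters, each refined into disjoint
sub-parameter sets.  The Cartesian product yields four sub-parametric
tuples; every expert supplies a CIFN for each tuple x tumour pair.  Six
patients carry susceptibility sub-intervals of [0, 1].

The study is exactly the published reference example this package's golden
tests reproduce; its expert opinions are hypothetical (committee-supplied),
not clinical measurements.
"""

from __future__ import annotations

from .study import StudyDocument

__all__ = ["brain_tumour_study"]

_ALTERNATIVES = ["craniopharyngioma", "brain-metastases", "medulloblastomas"]

_PARAMETERS = [
    {"name": "frontal-lobe-symptoms", "sub_parameters": ["sight-speech-problems", "loss-of-smell"]},
    {"name": "temporal-lobe-symptoms", "sub_parameters": ["short-term-memory-loss", "hearing-voices"]},
    {"name": "parietal-lobe-symptoms", "sub_parameters": ["loss-of-feeling-one-side"]},
    {"name": "occipital-lobe-symptoms", "sub_parameters": ["colour-size-identification"]},
]

# Tuple order is the Cartesian product of the sub-parameter sets above.
_TUPLES = [
    ["sight-speech-problems", "short-term-memory-loss", "loss-of-feeling-one-side", "colour-size-identification"],
    ["sight-speech-problems", "hearing-voices", "loss-of-feeling-one-side", "colour-size-identification"],
    ["loss-of-smell", "short-term-memory-loss", "loss-of-feeling-one-side", "colour-size-identification"],
    ["loss-of-smell", "hearing-voices", "loss-of-feeling-one-side", "colour-size-identification"],
]

# Per expert, per tuple: CIFNs [at, bt, af, bf] for the three tumour types,
# phases as fractions of 2*pi.
_OPINIONS: dict[str, list[list[list[float]]]] = {
    "Dm1": [
        [[0.12, 0.13, 0.13, 0.14], [0.14, 0.15, 0.15, 0.16], [0.16, 0.17, 0.13, 0.18]],
        [[0.22, 0.23, 0.23, 0.24], [0.24, 0.25, 0.25, 0.26], [0.26, 0.27, 0.23, 0.28]],
        [[0.32, 0.33, 0.33, 0.34], [0.34, 0.35, 0.35, 0.36], [0.36, 0.37, 0.33, 0.38]],
        [[0.42, 0.43, 0.43, 0.44], [0.44, 0.45, 0.45, 0.46], [0.46, 0.47, 0.43, 0.48]],
    ],
    "Dm2": [
        [[0.21, 0.31, 0.31, 0.41], [0.41, 0.51, 0.51, 0.61], [0.61, 0.71, 0.31, 0.81]],
        [[0.22, 0.32, 0.32, 0.42], [0.42, 0.52, 0.52, 0.62], [0.62, 0.72, 0.32, 0.82]],
        [[0.23, 0.33, 0.33, 0.43], [0.43, 0.53, 0.53, 0.63], [0.63, 0.73, 0.33, 0.83]],
        [[0.24, 0.34, 0.34, 0.44], [0.44, 0.54, 0.54, 0.64], [0.64, 0.74, 0.34, 0.84]],
    ],
    "Dm3": [
        [[0.24, 0.34, 0.34, 0.44], [0.44, 0.54, 0.54, 0.64], [0.64, 0.74, 0.34, 0.84]],
        [[0.23, 0.33, 0.33, 0.43], [0.43, 0.53, 0.53, 0.63], [0.63, 0.73, 0.33, 0.83]],
        [[0.22, 0.32, 0.32, 0.42], [0.42, 0.52, 0.52, 0.62], [0.62, 0.72, 0.32, 0.82]],
        [[0.52, 0.33, 0.13, 0.42], [0.34, 0.15, 0.25, 0.16], [0.46, 0.37, 0.43, 0.48]],
    ],
}

_PATIENTS = [
    {"name": "P1", "interval": (0.0, 0.3)},
    {"name": "P2", "interval": (0.2, 0.4)},
    {"name": "P3", "interval": (0.2, 0.6)},
    {"name": "P4", "interval": (0.3, 0.7)},
    {"name": "P5", "interval": (0.3, 0.85)},
    {"name": "P6", "interval": (0.85, 1.0)},
]


def brain_tumour_study() -> StudyDocument:
    """Build the bundled three-expert, four-tuple, six-patient study."""
    experts = [
        {
            "name": dm,
            "rows": [
                {
                    "tuple": list(t),
                    "approximations": {
                        alt: list(cifn) for alt, cifn in zip(_ALTERNATIVES, row)
                    },
                }
                for t, row in zip(_TUPLES, rows)
            ],
        }
        for dm, rows in _OPINIONS.items()
    ]
    return StudyDocument.model_validate(
        {
            "alternatives": list(_ALTERNATIVES),
            "parameters": [dict(p) for p in _PARAMETERS],
            "experts": experts,
            "patients": [{"name": p["name"], "interval": list(p["interval"])} for p in _PATIENTS],
        }
    )
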