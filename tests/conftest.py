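import hypothesis
import pytest
from hypothesis import strategies as st

from fphss import FPCIFHSS, FPRow, CIFN, brain_tumour_study

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    return brain_tumour_study()


@pytest.fixture(scope="session")
def opinion_matrices(study):
    return {m.decision_maker: m for m in study.opinion_matrices()}


# -- shared hypothesis strategies -------------------------------------------

_unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False, allow_infinity=False)


@st.composite
def cifns(draw, classical_phase: bool = False):
    """A valid CIFN; with ``classical_phase`` the phase sum is also bounded by 1."""
    at = draw(_unit)
    af = draw(st.floats(min_value=0.0, max_value=max(0.0, 1.0 - at), allow_nan=False))
    bt = draw(_unit)
    if classical_phase:
        bf = draw(st.floats(min_value=0.0, max_value=max(0.0, 1.0 - bt), allow_nan=False))
    else:
        bf = draw(_unit)
    return CIFN(at=at, bt=bt, af=af, bf=bf)


@st.composite
def approximations(draw, n_alternatives: int = 3):
    alts = [f"alt{i}" for i in range(n_alternatives)]
    return {alt: draw(cifns()) for alt in alts}


@st.composite
def fpcifhss_pairs(draw, n_tuples: int = 2, n_alternatives: int = 2):
    """Two structures sharing the same alternatives and tuple set."""
    alts = tuple(f"alt{i}" for i in range(n_alternatives))
    tuples = [(f"s{i}",) for i in range(n_tuples)]

    def one():
        rows = {
            t: FPRow(draw(_unit), {alt: draw(cifns()) for alt in alts}) for t in tuples
        }
        return FPCIFHSS(alts, rows)

    return one(), one()
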