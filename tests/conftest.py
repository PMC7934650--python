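import numpy as np
import pytest

from delimita.io import Alignment, MorphoMatrix, SequenceRecord, SpecimenRecord, TRAIT_CODES


def make_specimen(sid="S1", nest="N1", cwb=1000.0, label=None, **ratio_overrides):
    """A specimen whose traits are simple multiples of CWb.

    ``ratio_overrides`` maps trait code -> value in um (not a ratio); any
    trait not overridden defaults to 0.5 * CWb.
    """
    traits = {c: 0.5 * cwb for c in TRAIT_CODES}
    traits["CWb"] = cwb
    traits.update(ratio_overrides)
    return SpecimenRecord(sid, nest, traits, qualitative_label=label)


@pytest.fixture
def single_specimen_matrix():
    return MorphoMatrix([make_specimen()])


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            SequenceRecord("a", "ACGT"),
            SequenceRecord("b", "ACGA"),
            SequenceRecord("c", "AC-T"),
        ]
    )


@pytest.fixture(scope="session")
def study_bundle():
    """One fixed draw of the five-species study emulation (shared, read-only)."""
    from delimita.synth import simulate_study_bundle

    return simulate_study_bundle(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
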