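import numpy as np
import pytest

import nsphere as ns


@pytest.fixture(scope="session")
def classic():
    return ns.canonical_model("three-shell-classic")


@pytest.fixture(scope="session")
def classic_constants(classic):
    return ns.harmonic_constants(classic, 100)


@pytest.fixture(scope="session")
def classic4(classic):
    """Classic model padded to four shells by splitting the skull."""
    return ns.split_shell(classic, 2)


def profile_error(a, b):
    """Max absolute difference normalized by the largest oracle magnitude.

    Potentials cross zero along any profile, so pointwise ratios are
    meaningless there; the max-norm convention is what 'relative error of a
    profile' means throughout this suite.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    return float(np.max(np.abs(a - b)) / np.max(np.abs(b)))
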