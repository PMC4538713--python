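"""Shared fixtures: phantom, simulated sessions, registration products.

Session-scoped fixtures keep the expensive simulated sessions to one
construction per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

import navmc
from navmc import synthetic


@pytest.fixture(scope="session")
def phantom():
    """Default phantom rendered once: (spec, pet_truth, mr_truth, masks)."""
    spec = synthetic.PhantomSpec()
    pet, mr, masks = synthetic.generate_phantom(spec)
    return spec, pet, mr, masks


@pytest.fixture(scope="session")
def session_8mm():
    """One preset session at 8 mm nod+slide motion (seed 1)."""
    return synthetic.preset_session(seed=1, max_motion_mm=8.0)


@pytest.fixture(scope="session")
def registered_8mm(session_8mm):
    """Burst-representative registrations of the 8 mm session.

    Returns (session, results, transforms) where transforms[0] is identity
    and transforms[n] is the registered pose of burst n's first navigator.
    """
    sess = session_8mm
    fixed = sess.navigators[0][0]
    results = [navmc.register_rigid(b[0], fixed) for b in sess.navigators[1:]]
    transforms = [navmc.identity()] + [r.transform for r in results]
    return sess, results, transforms


def rmse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    d = (np.asarray(a, float) - np.asarray(b, float))[mask]
    return float(np.sqrt(np.mean(d * d)))
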