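"""Shared fixtures: synthetic traces with analytic truth, built at test time."""

import numpy as np
import pytest

from curvatrace import FixtureSpec, fit_backbone_curve
from curvatrace.fixtures import helix_closed_form


@pytest.fixture(scope="session")
def helix_spec():
    return FixtureSpec.helix(30)


@pytest.fixture(scope="session")
def helix_coords(helix_spec):
    return helix_spec.coordinates()


@pytest.fixture(scope="session")
def helix_curve(helix_coords):
    return fit_backbone_curve(helix_coords, range(1, 31))


@pytest.fixture(scope="session")
def helix_truth():
    """Closed-form (kappa, tau) of the ideal alpha-helix fixture."""
    return helix_closed_form()


@pytest.fixture(scope="session")
def line_curve():
    spec = FixtureSpec.line(10)
    return fit_backbone_curve(spec.coordinates(), range(1, 11))


@pytest.fixture(scope="session")
def circle_curve():
    spec = FixtureSpec.circle(14, radius=10.0)
    # circle points 0.5 rad apart at R=10 are ~4.95 A apart: disable the
    # trace-continuity bond-length heuristic for this synthetic curve
    return fit_backbone_curve(spec.coordinates(), range(1, 15), max_ca_distance=np.inf)


def rigid_motion(rng):
    """A uniformly random rotation matrix and a random translation."""
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50.0, 50.0, 3)
    return q, t
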