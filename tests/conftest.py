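import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from optrecon.phantom import PhantomSpec, make_phantom, simulate_projections  # noqa: E402


@pytest.fixture(scope="session")
def disc_slice():
    """Uniform unit disc (radius N/4) on a 256 grid, with its mask pair."""
    n = 256
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    disc = (r2 <= (n / 4.0) ** 2).astype(float)
    inside = r2 <= (0.9 * n / 4.0) ** 2
    outside = (r2 > (1.2 * n / 4.0) ** 2) & (r2 < (0.95 * n / 2.0) ** 2)
    return disc, inside, outside


@pytest.fixture(scope="session")
def bead_slice_spec():
    """Standard sparse bead phantom slice used for undersampling studies."""
    return PhantomSpec(
        kind="beads", field_size=14.0, grid=128, n_slices=1, n_beads=40,
        n_projections=400, seed=11,
    )


@pytest.fixture(scope="session")
def bead_slice(bead_slice_spec):
    truth, table = make_phantom(bead_slice_spec)
    return truth.voxels[0], table


@pytest.fixture(scope="session")
def small_bead_stack():
    """Small multi-row bead stack for IO / volume-level tests."""
    spec = PhantomSpec(
        kind="beads", field_size=7.0, grid=64, n_slices=8, n_beads=12,
        n_projections=60, seed=4,
    )
    truth, table = make_phantom(spec)
    stack = simulate_projections(truth, spec)
    return stack, truth, table, spec


@pytest.fixture(scope="session")
def vessel_stack_spec():
    """Dense vessel stack used by alignment / bleach recovery tests."""
    return dict(
        kind="vessels", field_size=14.0, grid=96, n_slices=160,
        n_projections=32, seed=5, vessel_radius_px=2.5, n_vessels=8,
    )


@pytest.fixture(scope="session")
def vessel_truth(vessel_stack_spec):
    truth, _ = make_phantom(PhantomSpec(**vessel_stack_spec))
    return truth
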