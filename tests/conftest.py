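import numpy as np
import pytest

from nfkbdyn import (NFKB2_NULL, WT, build_system, reference_parameters,
                     steady_state)
from nfkbdyn.experiments import run_timecourse
from nfkbdyn.ikk import DEFAULT_BASAL, get_regime_profile


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def wt_system(ref_params):
    return build_system(WT, ref_params)


@pytest.fixture(scope="session")
def wt_steady(wt_system):
    return steady_state(wt_system, DEFAULT_BASAL)


@pytest.fixture(scope="session")
def ko_system(ref_params):
    return build_system(NFKB2_NULL, ref_params)


@pytest.fixture(scope="session")
def ko_steady(ko_system):
    return steady_state(ko_system, DEFAULT_BASAL)


# the three canonical stimulated time courses; run_timecourse memoises, so
# every test that needs one of these reuses the same integration
@pytest.fixture(scope="session")
def wt_tnfp(ref_params):
    return run_timecourse(WT, get_regime_profile("tnfp"), ref_params, 16.0)


@pytest.fixture(scope="session")
def wt_tnfc(ref_params):
    return run_timecourse(WT, get_regime_profile("tnfc"), ref_params, 16.0)


@pytest.fixture(scope="session")
def ko_tnfp(ref_params):
    return run_timecourse(NFKB2_NULL, get_regime_profile("tnfp"), ref_params,
                          16.0)


def value_at(traj, curve, t):
    """Interpolated value of a derived curve at time t."""
    return float(np.interp(t, traj.times, getattr(traj, curve)))
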