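"""Shared fixtures: the packaged study and the expensive session-scoped fits."""

import warnings

import numpy as np
import pytest

import sccosol as s
from sccosol import cubic_eos, semiempirical


@pytest.fixture(scope="session")
def study():
    return s.builtin_palbociclib_study()


@pytest.fixture(scope="session")
def fast_config():
    return semiempirical.OptimizerConfig(restarts=8)


@pytest.fixture(scope="session")
def se_fits(study):
    """Full-quality fits of all ten correlations to the packaged study."""
    cfg = semiempirical.OptimizerConfig(restarts=64)
    return semiempirical.fit_all(study, config=cfg)


@pytest.fixture(scope="session")
def vdw_fit(study):
    return cubic_eos.fit_eos(study, cubic_eos.MixingRuleSpec(kind="vdw"))


@pytest.fixture(scope="session")
def ws_fit(study):
    template = cubic_eos.MixingRuleSpec(
        kind="wong_sandler", ge_model=cubic_eos.GEModelSpec(kind="wilson")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cubic_eos.fit_eos(study, template)


@pytest.fixture(scope="session")
def pr_pair(study):
    """(ai, bi) arrays for the CO2/palbociclib pair at 308 K."""
    p1 = cubic_eos.pure_pr_params(study.solvent, 308.0)
    p2 = cubic_eos.pure_pr_params(study.solute, 308.0)
    return (
        np.array([p1.attraction, p2.attraction]),
        np.array([p1.covolume, p2.covolume]),
    )
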