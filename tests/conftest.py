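import numpy as np
import pytest

from forcematch import synthetic as syn


@pytest.fixture(scope="session")
def truth():
    """Default alkane-plausible ground-truth force field."""
    return syn.default_ground_truth()


@pytest.fixture(scope="session")
def pentane(truth):
    top, xyz = syn.ideal_geometry("n-pentane", truth.ff)
    return top, xyz


@pytest.fixture(scope="session")
def butane_pair(truth):
    """Two n-butane molecules at liquid-like contact."""
    return syn.make_cluster("n-butane", 2, seed=3)


@pytest.fixture(scope="session")
def pentane_cluster(truth):
    """Six n-pentane molecules at liquid-like contact."""
    return syn.make_cluster("n-pentane", 6, seed=11)


def numerical_forces(conf_coords, top, ff, h=1e-6, box=None):
    """Central-finite-difference −∇E oracle."""
    from forcematch.model import Conformation, total_energy_forces

    out = np.zeros_like(conf_coords)
    for i in range(top.n_atoms):
        for c in range(3):
            xp = conf_coords.copy()
            xp[i, c] += h
            xm = conf_coords.copy()
            xm[i, c] -= h
            ep = total_energy_forces(Conformation(xp, box=box), top, ff)[0]
            em = total_energy_forces(Conformation(xm, box=box), top, ff)[0]
            out[i, c] = -(ep - em) / (2.0 * h)
    return out


@pytest.fixture(scope="session")
def fd_forces():
    return numerical_forces
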