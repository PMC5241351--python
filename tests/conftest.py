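import numpy as np
import pytest

from mesomix import MixtureSpec, gen_random_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixture():
    """Atomistic 40-molecule 30 mol% mixture in a periodic box."""
    return gen_random_mixture(MixtureSpec(40, 30.0, seed=7), atomistic=True)


def brute_force_hbonds(config, criteria):
    """O(n²) all-pairs minimum-image enumeration of donor-H -> acceptor-O
    bonds; independent of the tree-based detector."""
    out = set()
    fold = max(criteria.angle_min_deg, 360.0 - criteria.angle_max_deg)
    o_atoms = np.flatnonzero(config.elements == "O")
    h_atoms = np.flatnonzero(config.donor_h)
    for hi in h_atoms:
        m_d = config.mol_index[hi]
        sel = config.molecule_atoms(m_d)
        oi_d = int(sel[config.elements[sel] == "O"][0])
        for ai in o_atoms:
            if config.mol_index[ai] == m_d:
                continue
            v_acc = config.box.min_image(config.coords[ai] - config.coords[hi])
            dist = float(np.linalg.norm(v_acc))
            if dist >= criteria.h_acceptor_max_A:
                continue
            v_don = config.box.min_image(config.coords[oi_d] - config.coords[hi])
            cosang = np.dot(v_don, v_acc) / (np.linalg.norm(v_don) * dist)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= fold:
                out.add((int(hi), int(ai)))
    return out
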