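"""Geometric hydrogen-bond detection and alcohol bonding-state classification.

A donor O-H ... acceptor O pair is a hydrogen bond when the H-to-acceptor
distance is below a cutoff (default 2.5 Å) and the donor-O-H...O angle at the
hydrogen is close to linear (default within 30° of 180°, i.e. the 150-210°
band folded onto the geometric [0, 180°] range). All distances, and the
acceptor position entering the angle, use the minimum-image convention.

Alcohol molecules are classified exclusively: bonded (as donor or acceptor)
to at least one other alcohol -> P-P; otherwise to at least one water -> P-W;
otherwise unbonded. The three percentages therefore sum to exactly 100.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ALCOHOL, WATER, MolecularConfiguration, Trajectory


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: angle band (degrees, symmetric about 180) and
    maximum H...acceptor-O separation (Å)."""

    angle_min_deg: float = 150.0
    angle_max_deg: float = 210.0
    h_acceptor_max_A: float = 2.5

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_min_deg <= 180.0 <= self.angle_max_deg):
            raise ValueError("need 0 < angle_min <= 180 <= angle_max")
        if self.h_acceptor_max_A <= 0:
            raise ValueError("distance cutoff must be positive")

    @property
    def folded_angle_min(self) -> float:
        """The band [angle_min, angle_max] folded onto [0, 180]: a geometric
        angle theta qualifies iff theta >= this value."""
        return max(self.angle_min_deg, 360.0 - self.angle_max_deg)


@dataclass(frozen=True)
class HBond:
    donor_molecule: int
    acceptor_molecule: int
    donor_species: str
    acceptor_species: str
    h_acceptor_distance: float
    angle_deg: float
    donor_h_atom: int = -1
    acceptor_o_atom: int = -1

    def key(self) -> tuple[int, int]:
        """Directed (donor-H atom, acceptor-O atom) identity."""
        return (self.donor_h_atom, self.acceptor_o_atom)


@dataclass(frozen=True)
class HBondSummary:
    """Trajectory-averaged percentages of alcohol molecules per bonding class."""

    pct_PP: float
    pct_PW: float
    pct_none: float
    n_alcohol: int
    n_frames: int

    def __post_init__(self) -> None:
        total = self.pct_PP + self.pct_PW + self.pct_none
        if self.n_alcohol > 0 and abs(total - 100.0) > 1e-9:
            raise ValueError(f"class percentages must sum to 100, got {total}")


def _donor_atoms(config: MolecularConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """(donor H atom indices, matching donor O atom indices)."""
    h_idx = np.flatnonzero(config.donor_h)
    o_of_mol = np.full(config.n_molecules, -1, dtype=np.intp)
    o_idx = np.flatnonzero(config.elements == "O")
    for i in o_idx:
        m = config.mol_index[i]
        if o_of_mol[m] < 0:
            o_of_mol[m] = i
    return h_idx, o_of_mol[config.mol_index[h_idx]]


def detect_hbonds(config: MolecularConfiguration,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All hydrogen bonds of a configuration.

    Donors are water O-H and alcohol hydroxyl O-H; acceptors are any oxygen;
    intra-molecular pairs are excluded. Each directed donor-H -> acceptor-O
    pair appears at most once (one H may bond several acceptors and vice
    versa). Point-mode configurations are rejected.
    """
    if not config.is_atomistic:
        raise ValueError("hydrogen-bond detection requires an atomistic configuration")
    periodic = config.box.require_uniform()
    h_idx, d_o_idx = _donor_atoms(config)
    a_idx = np.flatnonzero(config.elements == "O")
    if len(h_idx) == 0 or len(a_idx) == 0:
        return []
    coords = config.box.wrap(config.coords) if periodic else config.coords
    if periodic:
        L = config.box.lengths
        tree = cKDTree(coords[a_idx], boxsize=L)
    else:
        tree = cKDTree(coords[a_idx])
    cos_min = np.cos(np.radians(criteria.folded_angle_min))  # theta >= fold  <=>  cos <= cos(fold)
    bonds: list[HBond] = []
    neighbours = tree.query_ball_point(coords[h_idx], r=criteria.h_acceptor_max_A)
    for hi, neigh in zip(h_idx, neighbours):
        m_d = int(config.mol_index[hi])
        for k in neigh:
            ai = int(a_idx[k])
            m_a = int(config.mol_index[ai])
            if m_a == m_d:
                continue
            v_acc = config.box.min_image(coords[ai] - coords[hi])
            dist = float(np.linalg.norm(v_acc))
            if dist >= criteria.h_acceptor_max_A or dist < 1e-9:
                continue
            oi = _donor_o_for(config, hi)
            v_don = config.box.min_image(coords[oi] - coords[hi])
            denom = np.linalg.norm(v_don) * dist
            cosang = float(np.dot(v_don, v_acc) / denom)
            cosang = min(1.0, max(-1.0, cosang))
            if cosang <= cos_min + 1e-12:
                bonds.append(HBond(
                    donor_molecule=m_d, acceptor_molecule=m_a,
                    donor_species=str(config.species[m_d]),
                    acceptor_species=str(config.species[m_a]),
                    h_acceptor_distance=dist,
                    angle_deg=float(np.degrees(np.arccos(cosang))),
                    donor_h_atom=int(hi), acceptor_o_atom=ai))
    bonds.sort(key=lambda b: b.key())
    return bonds


def _donor_o_for(config: MolecularConfiguration, h_atom: int) -> int:
    """Covalent O of a donor hydrogen, from molecule topology (the molecule's
    single oxygen — configurations are template-built)."""
    m = config.mol_index[h_atom]
    sel = config.molecule_atoms(m)
    o = sel[config.elements[sel] == "O"]
    if len(o) == 0:
        raise ValueError(f"donor hydrogen {h_atom} has no oxygen in its molecule")
    return int(o[0])


def classify_alcohols(bonds: list[HBond], config: MolecularConfiguration) -> dict[int, str]:
    """Exclusive per-alcohol bonding class with P-P taking precedence over
    P-W; returns {alcohol molecule index: "PP" | "PW" | "none"}."""
    alcohol_mols = np.flatnonzero(config.species == ALCOHOL)
    partners: dict[int, set[str]] = {int(m): set() for m in alcohol_mols}
    for b in bonds:
        if b.donor_species == ALCOHOL:
            partners[b.donor_molecule].add(b.acceptor_species)
        if b.acceptor_species == ALCOHOL:
            partners[b.acceptor_molecule].add(b.donor_species)
    out: dict[int, str] = {}
    for m, ps in partners.items():
        if ALCOHOL in ps:
            out[m] = "PP"
        elif WATER in ps:
            out[m] = "PW"
        else:
            out[m] = "none"
    return out


def frame_percentages(config: MolecularConfiguration,
                      criteria: HBondCriteria = HBondCriteria()) -> tuple[float, float, float]:
    """Per-frame (pct_PP, pct_PW, pct_none) over alcohol molecules."""
    classes = classify_alcohols(detect_hbonds(config, criteria), config)
    n = len(classes)
    if n == 0:
        return (0.0, 0.0, 0.0)
    counts = {"PP": 0, "PW": 0, "none": 0}
    for c in classes.values():
        counts[c] += 1
    return tuple(100.0 * counts[k] / n for k in ("PP", "PW", "none"))


def summarize_trajectory(traj: Trajectory, criteria: HBondCriteria = HBondCriteria(),
                         window_ps: float | None = 1000.0) -> HBondSummary:
    """Mean over trailing frames of the per-frame class percentages.

    The window defaults to the final 1 ns (all frames when the trajectory is
    shorter or carries no frame interval).
    """
    frames = traj.trailing(window_ps)
    if not frames:
        raise ValueError("empty frame window")
    pcts = np.array([frame_percentages(fr, criteria) for fr in frames])
    n_alc = int(np.sum(frames[0].species == ALCOHOL))
    pp, pw, none = pcts.mean(axis=0)
    if n_alc > 0:
        none = 100.0 - pp - pw  # guard float drift so the classes close exactly
    return HBondSummary(pct_PP=float(pp), pct_PW=float(pw), pct_none=float(none),
                        n_alcohol=n_alc, n_frames=len(frames))
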