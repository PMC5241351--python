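"""Synthetic configurations, trajectories and thermograms with known ground truth.

The generators stand in for an MD engine and a pressure-perturbation
calorimeter: randomly mixed and deliberately clustered binary water/alcohol
boxes (the former doubling as the random-mixture null of the segregation
statistic), hand-specified hydrogen-bond toy geometries, and thermograms with
baseline drift plus pressure-pulse spikes of planted area. All generators are
pure functions of (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ALCOHOL, WATER, MolecularConfiguration, SimulationBox, Thermogram, Trajectory

# per-molecule liquid volumes (Å^3) from molar volumes at 25 °C:
# water 18.07 cm^3/mol, 2-propanol 76.92 cm^3/mol
_V_WATER_A3 = 30.01
_V_ALCOHOL_A3 = 127.73

# rigid ideal geometries (Å, degrees)
_OH = 0.96
_HOH_ANGLE = 104.5
_CC = 1.53
_CO = 1.43
_COH_ANGLE = 108.5


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_box(n_molecules: int, alcohol_mole_percent: float) -> SimulationBox:
    """Cubic periodic box with the ideal-mixing liquid volume of the mixture."""
    n_alc = _round_half_up(n_molecules * alcohol_mole_percent / 100.0)
    vol = n_alc * _V_ALCOHOL_A3 + (n_molecules - n_alc) * _V_WATER_A3
    edge = vol ** (1.0 / 3.0)
    return SimulationBox((edge, edge, edge))


@dataclass(frozen=True)
class MixtureSpec:
    """Composition, box and seed of a binary water/alcohol mixture."""

    n_molecules: int
    alcohol_mole_percent: float
    box: SimulationBox | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not 0.0 <= self.alcohol_mole_percent <= 100.0:
            raise ValueError("alcohol_mole_percent must be in [0, 100]")
        if self.box is None:
            object.__setattr__(self, "box", estimate_box(self.n_molecules, self.alcohol_mole_percent))

    @property
    def n_alcohol(self) -> int:
        # round-half-up: deterministic and exact for e.g. 3000 x 2.5% = 75
        return _round_half_up(self.n_molecules * self.alcohol_mole_percent / 100.0)

    @property
    def n_water(self) -> int:
        return self.n_molecules - self.n_alcohol


@dataclass(frozen=True)
class ClusterSpec:
    """Planted-segregation ground truth for :func:`gen_clustered_mixture`."""

    n_clusters: int = 1
    cluster_sigma: float = 3.0       # Å, Gaussian displacement sd around a center
    clustered_fraction: float = 1.0  # fraction of alcohol molecules placed in clusters

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.cluster_sigma <= 0:
            raise ValueError("n_clusters and cluster_sigma must be positive")
        if not 0.0 <= self.clustered_fraction <= 1.0:
            raise ValueError("clustered_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# rigid-molecule templates
# ---------------------------------------------------------------------------

def _water_template() -> tuple[list[str], np.ndarray]:
    half = math.radians(_HOH_ANGLE / 2.0)
    h1 = _OH * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = _OH * np.array([-math.sin(half), 0.0, math.cos(half)])
    return ["O", "H", "H"], np.array([[0.0, 0.0, 0.0], h1, h2])


def _alcohol_template() -> tuple[list[str], np.ndarray]:
    # tetrahedral directions at the central carbon
    t1 = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
    t2 = np.array([1.0, -1.0, -1.0]) / math.sqrt(3)
    t3 = np.array([-1.0, 1.0, -1.0]) / math.sqrt(3)
    c0 = np.zeros(3)
    cm1, cm2 = _CC * t2, _CC * t3
    o = _CO * t1
    # hydroxyl H at 0.96 Å from O, C-O-H angle 108.5 deg
    u = t1                                   # C->O direction
    w = t2 - np.dot(t2, u) * u
    w /= np.linalg.norm(w)
    ang = math.radians(180.0 - _COH_ANGLE)
    h = o + _OH * (math.cos(ang) * u + math.sin(ang) * w)
    return ["C", "C", "C", "O", "H"], np.array([c0, cm1, cm2, o, h])


_WATER_ELS, _WATER_XYZ = _water_template()
_ALC_ELS, _ALC_XYZ = _alcohol_template()


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    """Unit quaternions (n,4) -> rotation matrices (n,3,3)."""
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
    ], axis=1)


def _build_config(points: np.ndarray, quats: np.ndarray, species: np.ndarray,
                  box: SimulationBox, atomistic: bool,
                  time_ps: float | None = None) -> MolecularConfiguration:
    if not atomistic:
        return MolecularConfiguration(species=species, box=box, points=box.wrap(points),
                                      time_ps=time_ps)
    rot = _quats_to_matrices(quats)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    mol_index: list[int] = []
    donor: list[bool] = []
    for m, sp in enumerate(species):
        els, xyz = (_WATER_ELS, _WATER_XYZ) if sp == WATER else (_ALC_ELS, _ALC_XYZ)
        pos = points[m] + xyz @ rot[m].T
        elements.extend(els)
        coords.append(pos)
        mol_index.extend([m] * len(els))
        donor.extend(e == "H" for e in els)
    cfg = MolecularConfiguration(
        species=species, box=box,
        elements=np.asarray(elements, dtype=object),
        coords=box.wrap(np.vstack(coords)),
        mol_index=np.asarray(mol_index, dtype=np.intp),
        time_ps=time_ps,
        donor_h=np.asarray(donor, dtype=bool),
    )
    return cfg


# ---------------------------------------------------------------------------
# mixture generators
# ---------------------------------------------------------------------------

def _draw_points_quats(spec: MixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = spec.box.lengths
    points = rng.uniform(0.0, 1.0, size=(spec.n_molecules, 3)) * L
    quats = rng.standard_normal(size=(spec.n_molecules, 4))
    return points, quats


def _species_array(spec: MixtureSpec) -> np.ndarray:
    return np.asarray([ALCOHOL] * spec.n_alcohol + [WATER] * spec.n_water, dtype=object)


def gen_random_mixture(spec: MixtureSpec, atomistic: bool = True) -> MolecularConfiguration:
    """Uniformly random mixture: molecule reference points uniform in the box,
    orientations uniform on SO(3) (quaternion sampling); overlaps permitted.

    This is the construction behind the random-mixture (ideal) null of the
    segregation statistic.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    points, quats = _draw_points_quats(spec, rng)
    return _build_config(points, quats, _species_array(spec), spec.box, atomistic)


def gen_clustered_mixture(spec: MixtureSpec, cluster: ClusterSpec,
                          atomistic: bool = True) -> MolecularConfiguration:
    """Mixture with planted alcohol clusters.

    ``clustered_fraction`` of the alcohol molecules are re-placed as wrapped
    Gaussian displacements (sd ``cluster_sigma``) around ``n_clusters``
    uniform centers (round-robin assignment); everything else is identical to
    :func:`gen_random_mixture` with the same seed, so ``clustered_fraction=0``
    reproduces it bit-exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    points, quats = _draw_points_quats(spec, rng)
    species = _species_array(spec)
    n_clustered = _round_half_up(cluster.clustered_fraction * spec.n_alcohol)
    if n_clustered > 0:
        crng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
        centers = crng.uniform(0.0, 1.0, size=(cluster.n_clusters, 3)) * spec.box.lengths
        disp = crng.normal(0.0, cluster.cluster_sigma, size=(n_clustered, 3))
        which = np.arange(n_clustered) % cluster.n_clusters
        points[:n_clustered] = spec.box.wrap(centers[which] + disp)
    return _build_config(points, quats, species, spec.box, atomistic)


def gen_mixture_trajectory(spec: MixtureSpec, n_frames: int,
                           cluster: ClusterSpec | None = None,
                           atomistic: bool = True,
                           frame_interval_ps: float = 0.4) -> Trajectory:
    """Trajectory of independent draws (random or clustered) with per-frame
    sub-seeds spawned deterministically from ``spec.seed``."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_frames) % (2 ** 31)
    frames = []
    for k in range(n_frames):
        fspec = MixtureSpec(spec.n_molecules, spec.alcohol_mole_percent, spec.box, int(seeds[k]))
        cfg = (gen_random_mixture(fspec, atomistic) if cluster is None
               else gen_clustered_mixture(fspec, cluster, atomistic))
        cfg.time_ps = k * frame_interval_ps
        frames.append(cfg)
    return Trajectory(frames, frame_interval_ps=frame_interval_ps)


# ---------------------------------------------------------------------------
# hydrogen-bond toy geometries
# ---------------------------------------------------------------------------

#: expected hydrogen-bond count of each toy case, by construction
TOY_EXPECTED_BONDS: dict[str, int] = {
    "collinear-pair": 1,
    "angle-149": 0,
    "angle-151": 1,
    "dist-2.49": 1,
    "dist-2.51": 0,
    "pbc-wrapped-pair": 1,
    "alcohol-donor": 1,
    "alcohol-acceptor": 1,
    "trifurcated": 3,
}

_TOY_BOX = SimulationBox((20.0, 20.0, 20.0))


def _toy_water(o: np.ndarray, h1: np.ndarray, h2: np.ndarray):
    return ["O", "H", "H"], np.array([o, h1, h2]), WATER


def _donor_water(o: np.ndarray):
    """Water donating along +z; the second H points sideways-down, away from
    any acceptor placed above."""
    h1 = o + np.array([0.0, 0.0, _OH])
    ang = math.radians(_HOH_ANGLE)
    h2 = o + _OH * np.array([math.sin(ang), 0.0, math.cos(ang)])
    return _toy_water(o, h1, h2)


def _acceptor_water(o: np.ndarray, outward: np.ndarray):
    """Water accepting at ``o`` with both hydrogens pointing outward (away
    from the donor side) so they cannot donate back."""
    u = outward / np.linalg.norm(outward)
    w = np.array([u[1] - u[2], u[2] - u[0], u[0] - u[1]])
    if np.linalg.norm(w) < 1e-9:
        w = np.array([1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)
    a = math.radians(30.0)
    h1 = o + _OH * u
    h2 = o + _OH * (math.cos(a) * u + math.sin(a) * w)
    return _toy_water(o, h1, h2)


def _pair_case(theta_deg: float, dist: float):
    """Donor water at the origin-side, acceptor water at H-O distance ``dist``
    making donor-O-H...O angle ``theta_deg`` (vertex at H)."""
    o_d = np.array([10.0, 10.0, 9.04])
    h = o_d + np.array([0.0, 0.0, _OH])
    phi = math.radians(180.0 - theta_deg)
    u = np.array([math.sin(phi), 0.0, math.cos(phi)])
    o_a = h + dist * u
    mols = [_donor_water(o_d), _acceptor_water(o_a, u)]
    return mols


def gen_hbond_toy(case_id: str) -> MolecularConfiguration:
    """Hand-specified geometries exercising the hydrogen-bond criterion; the
    expected bond count of each case is in :data:`TOY_EXPECTED_BONDS`."""
    if case_id not in TOY_EXPECTED_BONDS:
        raise ValueError(f"unknown toy case {case_id!r}; known: {sorted(TOY_EXPECTED_BONDS)}")
    if case_id == "collinear-pair":
        mols = _pair_case(180.0, 1.80)
    elif case_id == "angle-149":
        mols = _pair_case(149.0, 1.80)
    elif case_id == "angle-151":
        mols = _pair_case(151.0, 1.80)
    elif case_id == "dist-2.49":
        mols = _pair_case(180.0, 2.49)
    elif case_id == "dist-2.51":
        mols = _pair_case(180.0, 2.51)
    elif case_id == "pbc-wrapped-pair":
        o_d = np.array([10.0, 10.0, 19.0])
        h = o_d + np.array([0.0, 0.0, _OH])      # wraps to z = 19.96
        o_a = np.array([10.0, 10.0, 1.76])       # 1.80 Å from H through the image
        mols = [_donor_water(o_d), _acceptor_water(o_a, np.array([0.0, 0.0, 1.0]))]
    elif case_id == "alcohol-donor":
        # alcohol hydroxyl donates to a water above it
        o = np.array([10.0, 10.0, 9.0])
        h = o + np.array([0.0, 0.0, _OH])
        c1 = o + np.array([0.0, 0.0, -_CO])
        c2 = c1 + _CC * np.array([0.94, 0.0, -0.34])
        c3 = c1 + _CC * np.array([-0.94, 0.0, -0.34])
        alc = (["C", "C", "C", "O", "H"], np.array([c1, c2, c3, o, h]), ALCOHOL)
        wat = _acceptor_water(h + np.array([0.0, 0.0, 1.80]), np.array([0.0, 0.0, 1.0]))
        mols = [alc, wat]
    elif case_id == "alcohol-acceptor":
        # water donates to an alcohol hydroxyl oxygen
        o_d = np.array([10.0, 10.0, 9.0])
        mols = [_donor_water(o_d)]
        o_a = o_d + np.array([0.0, 0.0, _OH + 1.80])
        h_a = o_a + np.array([0.0, 0.0, _OH])               # points away from the donor
        c1 = o_a + _CO * np.array([0.94, 0.0, 0.34])
        c2 = c1 + _CC * np.array([0.94, 0.0, -0.34])
        c3 = c1 + _CC * np.array([0.34, 0.94, 0.0])
        mols.append((["C", "C", "C", "O", "H"], np.array([c1, c2, c3, o_a, h_a]), ALCOHOL))
    elif case_id == "trifurcated":
        # one donor H satisfying the criterion with three acceptors at once
        o_d = np.array([10.0, 10.0, 9.04])
        h = o_d + np.array([0.0, 0.0, _OH])
        mols = [_donor_water(o_d)]
        for theta, dist, psi in ((180.0, 1.8, 0.0), (165.0, 2.1, 120.0), (158.0, 2.3, 240.0)):
            phi, psi_r = math.radians(180.0 - theta), math.radians(psi)
            u = np.array([math.sin(phi) * math.cos(psi_r),
                          math.sin(phi) * math.sin(psi_r), math.cos(phi)])
            mols.append(_acceptor_water(h + dist * u, u))
    else:  # pragma: no cover
        raise AssertionError(case_id)
    elements, coords, mol_index, species = [], [], [], []
    for m, (els, xyz, sp) in enumerate(mols):
        elements.extend(els)
        coords.append(xyz)
        mol_index.extend([m] * len(els))
        species.append(sp)
    return MolecularConfiguration(
        species=np.asarray(species, dtype=object), box=_TOY_BOX,
        elements=np.asarray(elements, dtype=object), coords=np.vstack(coords),
        mol_index=np.asarray(mol_index, dtype=np.intp))


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermogramSpec:
    """Schedule and spike model of a synthetic PPC thermogram.

    Defaults follow the measurement protocol emulated here: ±4 bar pulses
    every 10 minutes at 1 °C intervals on a 0.1 °C·min⁻¹ ramp. ``spike_areas``
    maps each scheduled pulse temperature (°C) to the planted pressurization
    heat ΔQ (μJ); the up-pulse spike carries the sign of ΔQ and the following
    down-pulse mirrors it.
    """

    t_start_C: float
    t_end_C: float
    spike_areas: Mapping[float, float]
    pulse_interval_s: float = 600.0
    heating_rate_C_per_min: float = 0.1
    dp_bar: float = 4.0
    spike_model: str = "gauss"            # rect | gauss | expdecay
    spike_height_uW: float = 10.0         # rect height
    spike_sigma_s: float = 15.0           # gauss width
    spike_tau_s: float = 20.0             # expdecay time constant
    baseline_offset_uW: float = 0.0
    baseline_drift_uW_per_C: float = 0.0
    noise_sd_uW: float = 0.0
    sample_period_s: float = 1.0
    settle_s: float = 300.0               # lead-in before the first pulse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_start_C >= self.t_end_C:
            raise ValueError("t_start_C must be below t_end_C")
        if self.spike_model not in ("rect", "gauss", "expdecay"):
            raise ValueError(f"unknown spike model {self.spike_model!r}")

    @property
    def pulse_temps(self) -> np.ndarray:
        step = self.heating_rate_C_per_min * self.pulse_interval_s / 60.0
        n = int(math.floor((self.t_end_C - self.t_start_C) / step + 1e-9)) + 1
        return self.t_start_C + step * np.arange(n)


def _area_for(spec: ThermogramSpec, temp: float) -> float:
    for key, val in spec.spike_areas.items():
        if abs(float(key) - temp) < 1e-6:
            return float(val)
    raise ValueError(f"spike_areas defines no area for scheduled pulse temperature {temp:g} °C")


def gen_thermogram(spec: ThermogramSpec) -> Thermogram:
    """Synthesize a thermogram: linear ramp baseline (offset + drift per °C),
    one spike of planted area per pulse, Gaussian noise, alternating up/down
    events starting with an up-pulse."""
    temps_sched = spec.pulse_temps
    areas = np.array([_area_for(spec, T) for T in temps_sched])
    t_pulse = spec.settle_s + spec.pulse_interval_s * np.arange(len(temps_sched))
    total = t_pulse[-1] + spec.pulse_interval_s
    t = np.arange(0.0, total + spec.sample_period_s / 2, spec.sample_period_s)
    temp = spec.t_start_C + (t - spec.settle_s) * spec.heating_rate_C_per_min / 60.0
    power = spec.baseline_offset_uW + spec.baseline_drift_uW_per_C * (temp - spec.t_start_C)
    directions = np.where(np.arange(len(temps_sched)) % 2 == 0, "up", "down")
    for t0, area, direction in zip(t_pulse, areas, directions):
        a = area if direction == "up" else -area
        if spec.spike_model == "rect":
            # plateau starts one sample after the event; a fractional-height
            # trailing sample makes the sampled trapezoid equal the planted
            # area exactly for any duration
            dt = spec.sample_period_s
            h = spec.spike_height_uW
            m = int(math.floor(abs(a) / (h * dt)))
            i0 = int(np.searchsorted(t, t0))
            power[i0 + 1: i0 + 1 + m] += math.copysign(h, a)
            rem = abs(a) - h * m * dt
            if rem > 0 and i0 + 1 + m < len(power):
                power[i0 + 1 + m] += math.copysign(rem / dt, a)
        elif spec.spike_model == "gauss":
            c = t0 + 4.0 * spec.spike_sigma_s
            power += a * np.exp(-0.5 * ((t - c) / spec.spike_sigma_s) ** 2) / (
                spec.spike_sigma_s * math.sqrt(2.0 * math.pi))
        else:  # expdecay
            mask = t >= t0
            power[mask] += (a / spec.spike_tau_s) * np.exp(-(t[mask] - t0) / spec.spike_tau_s)
    if spec.noise_sd_uW > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        power = power + rng.normal(0.0, spec.noise_sd_uW, size=len(t))
    samples = pd.DataFrame({"time_s": t, "temp_C": temp, "power_uW": power})
    events = pd.DataFrame({"time_s": t_pulse, "direction": directions,
                           "dp_bar": np.full(len(t_pulse), float(spec.dp_bar))})
    return Thermogram(samples=samples, events=events)


# ---------------------------------------------------------------------------
# in-study fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> pd.DataFrame:
    """Packaged reference tables.

    ``table1``: measured pressurization heats ΔQ (μJ) at 25.5 °C, window
    gradients (as printed, mJ·bar⁻¹·K⁻¹ label) and kinematic viscosity versus
    2-propanol mole percent. ``table2``: simulated hydrogen-bond class
    percentages (P–P / P–W / none) and segregation non-ideality versus mole
    percent.
    """
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown fixture {name!r}; available: table1, table2")
    with resources.files("mesomix.fixtures").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)
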