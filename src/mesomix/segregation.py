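"""Mesoscale segregation statistic for binary mixtures.

A configuration's periodic box is divided into an equal-volume grid of
sub-boxes (default 10 x 10 x 10 = 1000). A water molecule occupies the single
cell holding its oxygen; an alcohol molecule occupies every distinct cell
holding at least one of its carbons (1-3 cells). Occupancy histograms,
normalized over all (cell, configuration) pairs, give the fraction N(x) of
sub-boxes containing x molecules of a species. The non-ideality statistic is
the Euclidean distance between the alcohol occupancy distribution of the
simulated ensemble and that of a matched randomly-mixed (ideal) ensemble:

    non_ideality = sqrt( sum_x [N_sim(x) - N_rand(x)]^2 )

Zero means statistically random mixing; larger values mean segregation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ALCOHOL, WATER, MolecularConfiguration, SimulationBox, Trajectory
from .synthetic import MixtureSpec, gen_random_mixture


@dataclass(frozen=True)
class PartitionSpec:
    """Equal-sized sub-box grid of the simulation cell."""

    grid_shape: tuple[int, int, int] = (10, 10, 10)

    def __post_init__(self) -> None:
        g = tuple(int(x) for x in self.grid_shape)
        if len(g) != 3 or any(x <= 0 for x in g):
            raise ValueError("grid_shape must be three positive integers")
        object.__setattr__(self, "grid_shape", g)

    @property
    def n_boxes(self) -> int:
        return int(np.prod(self.grid_shape))

    @classmethod
    def auto(cls, n_molecules: int, target_occupancy: float = 3.0) -> "PartitionSpec":
        """Near-cubic grid preserving a mean occupancy of ~3 molecules per
        sub-box (3000 molecules -> 10 x 10 x 10), for scaled-down systems."""
        m = max(1, round((n_molecules / target_occupancy) ** (1.0 / 3.0)))
        return cls((m, m, m))


@dataclass
class OccupancyDistribution:
    """Fraction of (sub-box, configuration) pairs with occupancy x.

    ``fractions[x]`` is N(x); entries sum to 1 and are non-negative.
    """

    fractions: np.ndarray
    n_boxes_total: int
    species: str

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {self.fractions.sum()!r}")

    def as_dict(self) -> dict[int, float]:
        return {x: float(f) for x, f in enumerate(self.fractions) if f > 0}


@dataclass
class NonIdealityResult:
    value: float
    sim_distribution: OccupancyDistribution
    null_distribution: OccupancyDistribution
    sim_ensemble_size: int
    null_ensemble_size: int
    seed: int | None = None


def _cell_indices(coords: np.ndarray, box: SimulationBox, grid: tuple[int, int, int]) -> np.ndarray:
    """Flat cell index per coordinate; half-open cells [0, L/n) after wrapping."""
    wrapped = box.wrap(coords)
    g = np.asarray(grid)
    idx = np.floor(wrapped / (box.lengths / g)).astype(np.intp)
    idx = np.minimum(idx, g - 1)  # guard the L-epsilon edge
    return np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid)


def count_occupancy(config: MolecularConfiguration,
                    part: PartitionSpec = PartitionSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Per-sub-box (water_count, alcohol_count) arrays of length ``n_boxes``.

    Atomistic mode applies the oxygen rule for water and the carbon-presence
    rule for alcohol (an alcohol is counted once in each distinct cell that
    contains at least one of its carbons). Point mode bins the per-molecule
    reference point for both species.
    """
    if not config.box.require_uniform():
        raise ValueError("occupancy counting requires a periodic box")
    n_boxes = part.n_boxes
    water_counts = np.zeros(n_boxes, dtype=np.intp)
    alcohol_counts = np.zeros(n_boxes, dtype=np.intp)
    if config.is_atomistic:
        is_water_mol = config.species[config.mol_index] == WATER
        o_mask = (config.elements == "O") & is_water_mol
        if o_mask.any():
            cells = _cell_indices(config.coords[o_mask], config.box, part.grid_shape)
            np.add.at(water_counts, cells, 1)
        c_mask = (config.elements == "C") & ~is_water_mol
        if c_mask.any():
            cells = _cell_indices(config.coords[c_mask], config.box, part.grid_shape)
            mols = config.mol_index[c_mask]
            pairs = np.unique(np.stack([mols, cells], axis=1), axis=0)
            np.add.at(alcohol_counts, pairs[:, 1], 1)
    else:
        cells = _cell_indices(config.points, config.box, part.grid_shape)
        is_alc = config.species == ALCOHOL
        np.add.at(water_counts, cells[~is_alc], 1)
        np.add.at(alcohol_counts, cells[is_alc], 1)
    return water_counts, alcohol_counts


def build_distribution(count_arrays: Iterable[np.ndarray], species: str) -> OccupancyDistribution:
    """Normalized occupancy histogram over an ensemble of per-box counts."""
    arrays = [np.asarray(a) for a in count_arrays]
    if not arrays:
        raise ValueError("empty ensemble")
    flat = np.concatenate(arrays)
    hist = np.bincount(flat)
    total = len(flat)
    return OccupancyDistribution(fractions=hist / total, n_boxes_total=total, species=species)


def non_ideality(sim: OccupancyDistribution, null: OccupancyDistribution,
                 seed: int | None = None) -> NonIdealityResult:
    """Euclidean distance between two occupancy distributions (union of
    support, missing entries zero-filled)."""
    if sim.species != null.species:
        raise ValueError(f"distributions are over different species: {sim.species} vs {null.species}")
    n = max(len(sim.fractions), len(null.fractions))
    a = np.zeros(n)
    b = np.zeros(n)
    a[:len(sim.fractions)] = sim.fractions
    b[:len(null.fractions)] = null.fractions
    value = float(np.sqrt(np.sum((a - b) ** 2)))
    return NonIdealityResult(value=value, sim_distribution=sim, null_distribution=null,
                             sim_ensemble_size=sim.n_boxes_total,
                             null_ensemble_size=null.n_boxes_total, seed=seed)


def sample_null_ensemble(spec: MixtureSpec, part: PartitionSpec = PartitionSpec(),
                         n_configs: int = 2500, atomistic: bool = False,
                         species: str = ALCOHOL) -> OccupancyDistribution:
    """Occupancy distribution of an ensemble of independent random mixtures
    matched in composition and box volume (the ideal-mixing null).

    Per-configuration seeds are spawned deterministically from ``spec.seed``.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_configs) % (2 ** 31)
    counts = []
    for k in range(n_configs):
        cfg = gen_random_mixture(
            MixtureSpec(spec.n_molecules, spec.alcohol_mole_percent, spec.box, int(seeds[k])),
            atomistic=atomistic)
        w, a = count_occupancy(cfg, part)
        counts.append(a if species == ALCOHOL else w)
    return build_distribution(counts, species)


def ensemble_distribution(configs: Iterable[MolecularConfiguration],
                          part: PartitionSpec = PartitionSpec(),
                          species: str = ALCOHOL) -> OccupancyDistribution:
    """Occupancy distribution of an explicit ensemble (e.g. trajectory frames)."""
    counts = []
    for cfg in configs:
        w, a = count_occupancy(cfg, part)
        counts.append(a if species == ALCOHOL else w)
    return build_distribution(counts, species)


def trajectory_non_ideality(traj: Trajectory, spec: MixtureSpec | None = None,
                            part: PartitionSpec = PartitionSpec(),
                            n_null_configs: int | None = None,
                            max_frames: int = 2500,
                            species: str = ALCOHOL,
                            seed: int = 0) -> NonIdealityResult:
    """Non-ideality of a trajectory against its matched random null.

    The simulated distribution uses the trailing ``max_frames`` frames
    (default 2500, or all frames if fewer). Unless given explicitly, the null
    is matched on the final frame's composition and box volume and on the
    ensemble size. The null runs in atomistic mode iff the trajectory is
    atomistic, so the carbon-presence rule acts on both sides.
    """
    frames = list(traj.frames[-max_frames:])
    final = frames[-1]
    if spec is None:
        n_alc = int(np.sum(final.species == ALCOHOL))
        spec = MixtureSpec(final.n_molecules, 100.0 * n_alc / final.n_molecules,
                           final.box, seed)
    sim = ensemble_distribution(frames, part, species)
    null = sample_null_ensemble(spec, part,
                                n_configs=n_null_configs or len(frames),
                                atomistic=final.is_atomistic, species=species)
    res = non_ideality(sim, null, seed=spec.seed)
    res.sim_ensemble_size = len(frames)
    res.null_ensemble_size = n_null_configs or len(frames)
    return res
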