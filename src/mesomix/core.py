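"""Core domain containers for mixture-structure analysis.

All coordinates and box lengths are in angstrom (Å); times in picoseconds
on the simulation side and seconds on the calorimetry side; temperatures in
degrees Celsius at I/O boundaries (converted to kelvin only inside
thermodynamic equations).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WATER = "water"
ALCOHOL = "alcohol"

#: covalent O-H cutoff used once, at construction time, to flag hydroxyl /
#: water hydrogens as potential donors (Å)
COVALENT_OH_MAX = 1.2


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    edge_lengths : (Lx, Ly, Lz) in Å, all positive.
    periodic : per-axis periodicity flags. Consumers require the flags to be
        uniform (all periodic or all open); mixed flags are rejected there.
    """

    edge_lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        L = tuple(float(x) for x in self.edge_lengths)
        if len(L) != 3 or any(not np.isfinite(x) or x <= 0 for x in L):
            raise ValueError(f"box edge lengths must be three positive numbers, got {self.edge_lengths}")
        object.__setattr__(self, "edge_lengths", L)
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def all_periodic(self) -> bool:
        return all(self.periodic)

    def require_uniform(self) -> bool:
        """Return True if fully periodic, False if fully open; raise on mixed flags."""
        if all(self.periodic):
            return True
        if not any(self.periodic):
            return False
        raise ValueError(f"mixed periodic flags {self.periodic} are not supported by analysis operations")

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) along periodic axes."""
        coords = np.asarray(coords, dtype=float)
        out = coords.copy()
        L = self.lengths
        for ax in range(3):
            if self.periodic[ax]:
                out[..., ax] = np.mod(out[..., ax], L[ax])
                # mod can return exactly L for tiny negative inputs
                out[..., ax] = np.where(out[..., ax] >= L[ax], 0.0, out[..., ax])
        return out

    def min_image(self, delta: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        delta = np.asarray(delta, dtype=float)
        out = delta.copy()
        L = self.lengths
        for ax in range(3):
            if self.periodic[ax]:
                out[..., ax] -= L[ax] * np.round(out[..., ax] / L[ax])
        return out


def _infer_donor_h(elements: np.ndarray, coords: np.ndarray, mol_index: np.ndarray,
                   species: np.ndarray) -> np.ndarray:
    """Flag donor-capable hydrogens: every water H; alcohol H within covalent
    range of the hydroxyl O. Assigned once at construction and treated as
    topology afterwards."""
    donor = np.zeros(len(elements), dtype=bool)
    for m in np.unique(mol_index):
        sel = np.flatnonzero(mol_index == m)
        els = elements[sel]
        if species[m] == WATER:
            donor[sel[els == "H"]] = True
        else:
            o_idx = sel[els == "O"]
            if len(o_idx) == 0:
                continue
            o_pos = coords[o_idx[0]]
            for i in sel[els == "H"]:
                if np.linalg.norm(coords[i] - o_pos) <= COVALENT_OH_MAX:
                    donor[i] = True
    return donor


@dataclass
class MolecularConfiguration:
    """A single particle configuration of a binary water/alcohol mixture.

    Two storage modes exist:

    * atomistic — ``elements``/``coords``/``mol_index`` populated, one row per
      atom; hydrogen-bond and carbon-presence analyses are available.
    * point (united-atom) — ``points`` holds one reference coordinate per
      molecule and the atom arrays are empty; only occupancy/segregation
      analyses accept such configurations.
    """

    species: np.ndarray                       # (n_molecules,) of {"water","alcohol"}
    box: SimulationBox
    elements: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    mol_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    points: np.ndarray | None = None          # (n_molecules, 3) in point mode
    time_ps: float | None = None
    donor_h: np.ndarray | None = None         # per-atom flag, derived if absent

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.mol_index = np.asarray(self.mol_index, dtype=np.intp)
        bad = set(self.species) - {WATER, ALCOHOL}
        if bad:
            raise ValueError(f"unknown species labels {sorted(bad)}")
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
            if len(self.points) != self.n_molecules:
                raise ValueError("points must have one row per molecule")
        if len(self.elements) != len(self.coords) or len(self.elements) != len(self.mol_index):
            raise ValueError("elements, coords and mol_index must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.is_atomistic:
            if self.mol_index.min(initial=0) < 0 or (len(self.mol_index) and self.mol_index.max() >= self.n_molecules):
                raise ValueError("mol_index out of range")
            if self.donor_h is None:
                self.donor_h = _infer_donor_h(self.elements, self.coords, self.mol_index, self.species)
            else:
                self.donor_h = np.asarray(self.donor_h, dtype=bool)
        elif self.points is None:
            raise ValueError("configuration needs either atoms or per-molecule points")

    # -- basic properties -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def is_atomistic(self) -> bool:
        return self.n_atoms > 0

    def molecule_atoms(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.mol_index == m)

    def reference_points(self) -> np.ndarray:
        """Per-molecule reference coordinate: stored points in point mode,
        the oxygen (water) / first carbon (alcohol) position otherwise."""
        if not self.is_atomistic:
            return self.points
        pts = np.zeros((self.n_molecules, 3))
        for m in range(self.n_molecules):
            sel = self.molecule_atoms(m)
            target = "O" if self.species[m] == WATER else "C"
            cand = sel[self.elements[sel] == target]
            pts[m] = self.coords[cand[0] if len(cand) else sel[0]]
        return pts

    def validate(self) -> None:
        """Enforce per-molecule composition invariants (atomistic mode)."""
        if not self.is_atomistic:
            return
        for m in range(self.n_molecules):
            sel = self.molecule_atoms(m)
            els = list(self.elements[sel])
            if len(sel) == 0:
                raise ValueError(f"molecule {m} has no atoms")
            if self.species[m] == WATER:
                if els.count("O") != 1:
                    raise ValueError(f"water molecule {m} must contain exactly one O")
            else:
                if els.count("O") != 1 or els.count("C") != 3:
                    raise ValueError(f"alcohol molecule {m} must contain one hydroxyl O and three C")
                if not self.donor_h[sel].any():
                    raise ValueError(f"alcohol molecule {m} has no hydroxyl hydrogen")

    def translated(self, shift: Sequence[float]) -> "MolecularConfiguration":
        """Rigidly translate all coordinates (wrapped into the box)."""
        shift = np.asarray(shift, dtype=float)
        return MolecularConfiguration(
            species=self.species.copy(), box=self.box,
            elements=self.elements.copy(),
            coords=self.box.wrap(self.coords + shift) if self.n_atoms else self.coords,
            mol_index=self.mol_index.copy(),
            points=None if self.points is None else self.box.wrap(self.points + shift),
            time_ps=self.time_ps,
            donor_h=None if self.donor_h is None else self.donor_h.copy(),
        )


@dataclass
class Trajectory:
    """Ordered frames sharing molecule count and species labels."""

    frames: list[MolecularConfiguration]
    frame_interval_ps: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("trajectory needs at least one frame")
        first = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.n_molecules != first.n_molecules or not np.array_equal(fr.species, first.species):
                raise ValueError(f"frame {i} does not share molecule count/species with frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def trailing(self, window_ps: float | None) -> list[MolecularConfiguration]:
        """Frames spanning the final ``window_ps`` (all frames if the window
        is undefined, non-positive, or longer than the trajectory)."""
        if not window_ps or window_ps <= 0 or self.frame_interval_ps <= 0:
            return list(self.frames)
        n = int(round(window_ps / self.frame_interval_ps))
        n = max(1, min(n, len(self.frames)))
        return list(self.frames[-n:])


@dataclass
class Thermogram:
    """Differential-power time series with pressure-event annotations.

    ``samples``: DataFrame with columns ``time_s``, ``temp_C``, ``power_uW``
    (time strictly increasing). ``events``: DataFrame with columns ``time_s``,
    ``direction`` ("up"/"down"), ``dp_bar`` (> 0); event times must fall
    inside the sampled range.
    """

    samples: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.samples
        for col in ("time_s", "temp_C", "power_uW"):
            if col not in s.columns:
                raise ValueError(f"samples missing column {col!r}")
        t = s["time_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"sample times must be strictly increasing (first violation at row {bad})")
        e = self.events
        for col in ("time_s", "direction", "dp_bar"):
            if col not in e.columns:
                raise ValueError(f"events missing column {col!r}")
        if len(e):
            if not set(e["direction"]) <= {"up", "down"}:
                raise ValueError("event direction must be 'up' or 'down'")
            if (e["dp_bar"] <= 0).any():
                raise ValueError("event magnitudes must be positive")
            et = e["time_s"].to_numpy()
            if len(t) and ((et < t[0]) | (et > t[-1])).any():
                raise ValueError("event times must lie within the sampled time range")
        self.events = e.sort_values("time_s").reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def temperature_at(self, time_s: float) -> float:
        s = self.samples
        return float(np.interp(time_s, s["time_s"], s["temp_C"]))
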