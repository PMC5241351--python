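"""Readers/writers for particle configurations and thermograms.

Supported formats: XYZ with ``key=value`` comment-line metadata (``box=`` and
``time=``), a PDB subset (ATOM/HETATM + orthorhombic CRYST1), formatted
DL_POLY HISTORY (read-only, via MDAnalysis), and thermogram CSV.
"""
from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (ALCOHOL, WATER, FormatError, MolecularConfiguration,
                   SimulationBox, Thermogram, Trajectory)

# Each template: (species, block size, element multiset). Tried in order at
# every scan position; molecules are contiguous atom blocks.
SpeciesRule = Sequence[tuple[str, int, Mapping[str, int]]]
DEFAULT_SPECIES_RULE: SpeciesRule = (
    (WATER, 3, {"O": 1, "H": 2}),
    (ALCOHOL, 5, {"C": 3, "O": 1, "H": 1}),      # heavy atoms + hydroxyl H
    (ALCOHOL, 12, {"C": 3, "O": 1, "H": 8}),     # fully protonated 2-propanol
)

DEFAULT_RESNAME_MAP: Mapping[str, str] = {
    "HOH": WATER, "WAT": WATER, "SOL": WATER, "TIP3": WATER,
    "IPA": ALCOHOL, "IPL": ALCOHOL, "IPR": ALCOHOL,
}


def group_molecules(elements: Sequence[str], rule: SpeciesRule = DEFAULT_SPECIES_RULE,
                    *, line_offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Assign contiguous atom blocks to molecules by template matching.

    Matching is order-insensitive within a block. Returns (mol_index per atom,
    species per molecule). Raises :class:`FormatError` naming the first atom
    line of an unmatchable block.
    """
    elements = list(elements)
    n = len(elements)
    mol_index = np.empty(n, dtype=np.intp)
    species: list[str] = []
    i = 0
    while i < n:
        for sp, size, comp in rule:
            if i + size <= n and Counter(elements[i:i + size]) == dict(comp):
                mol_index[i:i + size] = len(species)
                species.append(sp)
                i += size
                break
        else:
            raise FormatError(
                f"atom block starting at line {line_offset + i + 1} (element {elements[i]!r}) "
                f"matches no molecule template")
    return mol_index, np.asarray(species, dtype=object)


def _fallback_box(coords: np.ndarray) -> SimulationBox:
    """Open (non-periodic) bounding box with 2 Å padding, for files without cell info."""
    span = coords.max(axis=0) - coords.min(axis=0) + 4.0
    span = np.maximum(span, 1.0)
    return SimulationBox(tuple(span), periodic=(False, False, False))


def _parse_comment(comment: str) -> dict:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key.strip().lower()] = val.strip()
    return out


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path, species_rule: SpeciesRule = DEFAULT_SPECIES_RULE,
             frame_interval_ps: float = 0.0) -> Trajectory:
    """Read a (multi-frame) XYZ file into a :class:`Trajectory`.

    The comment line may carry ``box=Lx,Ly,Lz`` (Å) and ``time=`` (ps);
    unknown keys are ignored. Without a box the frame gets an open bounding
    box and a warning is emitted.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularConfiguration] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].split()[0])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: line {ln + 1}: expected an atom count, got {lines[ln]!r}")
        meta = _parse_comment(lines[ln + 1] if ln + 1 < len(lines) else "")
        body = lines[ln + 2: ln + 2 + natoms]
        if len(body) < natoms:
            raise FormatError(f"{path}: frame starting at line {ln + 1} is truncated "
                              f"({len(body)} of {natoms} atom lines present)")
        elements, coords = [], []
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln + 3 + k}: malformed atom record {row!r}")
            elements.append(parts[0].capitalize())
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        coords = np.asarray(coords)
        try:
            mol_index, species = group_molecules(elements, species_rule, line_offset=ln + 2)
        except FormatError as err:
            raise FormatError(f"{path}: {err}") from None
        if "box" in meta:
            L = tuple(float(x) for x in meta["box"].split(","))
            box = SimulationBox(L)
        else:
            warnings.warn(f"{path}: no box= metadata on comment line; using an open bounding box")
            box = _fallback_box(coords)
        time_ps = float(meta["time"]) if "time" in meta else None
        frames.append(MolecularConfiguration(species=species, box=box, elements=np.asarray(elements, dtype=object),
                                             coords=coords, mol_index=mol_index, time_ps=time_ps))
        ln += 2 + natoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    if frame_interval_ps <= 0 and len(frames) >= 2:
        times = [f.time_ps for f in frames]
        if all(t is not None for t in times):
            frame_interval_ps = float(times[1] - times[0])
    return Trajectory(frames, frame_interval_ps=max(frame_interval_ps, 0.0))


def write_xyz(obj: Trajectory | MolecularConfiguration, path) -> None:
    """Write a configuration or trajectory as XYZ (coordinates to 6 decimals)."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    with open(path, "w") as fh:
        for fr in frames:
            if not fr.is_atomistic:
                raise ValueError("cannot write a point-mode configuration as XYZ")
            L = fr.box.edge_lengths
            comment = f"box={L[0]:.6f},{L[1]:.6f},{L[2]:.6f}"
            if fr.time_ps is not None:
                comment += f" time={fr.time_ps:.6f}"
            fh.write(f"{fr.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path, resname_map: Mapping[str, str] = DEFAULT_RESNAME_MAP) -> MolecularConfiguration:
    """Read a single-model PDB. Residue names map to species via
    ``resname_map``; non-orthorhombic CRYST1 angles are rejected; a missing
    CRYST1 yields an open box plus a warning."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        warnings.warn(f"{path}: missing CRYST1 record; treating the configuration as non-periodic")
        box = _fallback_box(u.atoms.positions)
    else:
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise FormatError(f"{path}: CRYST1 angles {tuple(dims[3:])} are not orthorhombic")
        box = SimulationBox(tuple(float(x) for x in dims[:3]))
    if hasattr(u.atoms, "elements") and all(e.strip() for e in u.atoms.elements):
        elements = np.asarray([e.capitalize() for e in u.atoms.elements], dtype=object)
    else:
        elements = np.asarray([nm.strip()[0].upper() for nm in u.atoms.names], dtype=object)
    species = []
    for res in u.residues:
        rn = res.resname.strip().upper()
        if rn not in resname_map:
            raise FormatError(f"{path}: residue name {rn!r} not in the species table")
        species.append(resname_map[rn])
    return MolecularConfiguration(species=np.asarray(species, dtype=object), box=box,
                                  elements=elements, coords=u.atoms.positions.astype(float),
                                  mol_index=u.atoms.resindices.astype(np.intp))


def write_pdb(config: MolecularConfiguration, path) -> None:
    """Write a configuration as PDB with CRYST1 (periodic boxes only)."""
    if not config.is_atomistic:
        raise ValueError("cannot write a point-mode configuration as PDB")
    resname = {WATER: "HOH", ALCOHOL: "IPA"}
    with open(path, "w") as fh:
        if config.box.all_periodic:
            L = config.box.edge_lengths
            fh.write(f"CRYST1{L[0]:9.3f}{L[1]:9.3f}{L[2]:9.3f}  90.00  90.00  90.00 P 1           1\n")
        counters: dict[int, int] = {}
        for i in range(config.n_atoms):
            m = int(config.mol_index[i])
            counters[m] = counters.get(m, 0) + 1
            el = str(config.elements[i])
            name = f"{el}{counters[m]}"
            x, y, z = config.coords[i]
            fh.write(f"ATOM  {i + 1:5d} {name:<4s}{resname[config.species[m]]:>4s} A{(m % 9999) + 1:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# DL_POLY HISTORY (formatted, read-only)
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = {"O": "O", "H": "H", "C": "C", "N": "N", "S": "S", "P": "P"}


def _element_from_name(name: str) -> str:
    stem = "".join(ch for ch in name if ch.isalpha())
    if not stem:
        raise FormatError(f"cannot infer an element from atom name {name!r}")
    two = stem[:2].capitalize()
    if two in ("Cl", "Na", "Mg", "Ca"):
        return two
    return _ELEMENT_FROM_NAME.get(stem[0].upper(), stem[0].upper())


def read_dlpoly_history(path, max_frames: int | None = None,
                        species_rule: SpeciesRule = DEFAULT_SPECIES_RULE) -> Trajectory:
    """Read a formatted DL_POLY HISTORY trajectory (coordinates only).

    Velocities/forces (levcfg 1/2) are skipped; triclinic cells are rejected;
    a truncated file raises naming the last complete frame.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="HISTORY", topology_format="HISTORY")
        except Exception as err:
            raise FormatError(f"{path}: not a readable formatted HISTORY file ({err})") from None
    elements = [_element_from_name(nm) for nm in u.atoms.names]
    mol_index, species = group_molecules(elements, species_rule)
    frames: list[MolecularConfiguration] = []

    def _append(ts) -> None:
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise FormatError(f"{path}: frame {len(frames)} has no usable cell")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise FormatError(f"{path}: triclinic cell in frame {len(frames)} is unsupported")
        frames.append(MolecularConfiguration(
            species=species, box=SimulationBox(tuple(float(x) for x in dims[:3])),
            elements=np.asarray(elements, dtype=object),
            coords=ts.positions.astype(float), mol_index=mol_index,
            time_ps=float(ts.time) if np.isfinite(ts.time) else None))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                _append(ts)
                if max_frames is not None and len(frames) >= max_frames:
                    break
    except FormatError:
        raise
    except Exception:
        raise FormatError(f"{path}: file truncated; last complete frame is "
                          f"{len(frames) - 1 if frames else 'none'} ({len(frames)} frames read)") from None
    if not frames:
        raise FormatError(f"{path}: no complete frames")
    dt = 0.0
    if len(frames) >= 2 and frames[0].time_ps is not None and frames[1].time_ps is not None:
        dt = frames[1].time_ps - frames[0].time_ps
    return Trajectory(frames, frame_interval_ps=max(dt, 0.0))


# ---------------------------------------------------------------------------
# Thermogram CSV
# ---------------------------------------------------------------------------

def read_thermogram_csv(path, events_path=None) -> Thermogram:
    """Read a thermogram CSV (columns ``time_s``, ``temp_C``, ``power_uW``).

    Pressure events come either from companion columns ``event_dir`` /
    ``event_dp_bar`` (non-empty on the row at event start) or from a sidecar
    table with columns ``time_s``, ``direction``, ``dp_bar``.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C", "power_uW"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy()
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise FormatError(f"{path}: time not strictly increasing at row {bad}")
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = ev[["time_s", "direction", "dp_bar"]].copy()
    elif "event_dir" in df.columns:
        mask = df["event_dir"].notna() & (df["event_dir"].astype(str).str.strip() != "")
        events = pd.DataFrame({
            "time_s": df.loc[mask, "time_s"].to_numpy(),
            "direction": df.loc[mask, "event_dir"].astype(str).str.strip().to_numpy(),
            "dp_bar": df.loc[mask, "event_dp_bar"].astype(float).to_numpy(),
        })
    else:
        events = pd.DataFrame(columns=["time_s", "direction", "dp_bar"])
    samples = df[["time_s", "temp_C", "power_uW"]].copy()
    return Thermogram(samples=samples, events=events)


def write_thermogram_csv(tg: Thermogram, path) -> None:
    """Write a thermogram with events as companion columns (lossless round-trip)."""
    df = tg.samples.copy()
    df["event_dir"] = ""
    df["event_dp_bar"] = np.nan
    t = df["time_s"].to_numpy()
    for _, ev in tg.events.iterrows():
        idx = int(np.argmin(np.abs(t - ev["time_s"])))
        df.iloc[idx, df.columns.get_loc("event_dir")] = ev["direction"]
        df.iloc[idx, df.columns.get_loc("event_dp_bar")] = ev["dp_bar"]
    df.to_csv(path, index=False, float_format="%.10g")
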