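"""Conformational-ensemble I/O and atom selections.

This module owns the unit and numbering conventions of the package:

* Internal length unit is the **nanometre** (GROMOS convention — the 0.2 nm
  clustering cutoff and all RMSD thresholds are stated in nm).  PDB files are
  in Angstrom; conversion happens exactly once, at the I/O boundary.
* Residue numbering is the *author numbering* of the input file, used
  verbatim.  No Kabat renumbering is performed: framework and CDR residue
  ranges are supplied explicitly by the user (inclusive on both ends).
* Alternate locations: altloc ``'A'`` or blank is kept, all others dropped.
  Insertion codes are part of residue identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import Atom as _BioAtom
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

NM_PER_ANGSTROM = 0.1

#: Backbone atom names used for the roto-translational fit by default.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Sentinel meaning "every atom of the residue, side chains included".
ALL = "ALL"


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: (chain, residue number, atom name) is the key."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str = ""
    insertion_code: str = ""

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.atom_name)


@dataclass
class AtomFrame:
    """A single conformation: atom metadata plus coordinates in nm."""

    atoms: tuple
    coordinates: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match atom count {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in frame")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom within frame: {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomFrame":
        """Return a copy with every coordinate mapped to R @ x + t."""
        new_xyz = self.coordinates @ np.asarray(rotation).T + np.asarray(translation)
        return AtomFrame(self.atoms, new_xyz)


@dataclass
class Ensemble:
    """One replicate trajectory: ordered frames plus an analysis window.

    ``window`` is a half-open frame-index interval ``[start, end)``.  The
    stored frames are never modified by windowing; analyses iterate only
    over the windowed part.
    """

    frames: list
    frame_times: Sequence[float] | None = None  # ps, optional
    window: tuple = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        ref = self.frames[0]
        ref_keys = tuple(a.key for a in ref.atoms)
        for i, fr in enumerate(self.frames[1:], start=2):
            if tuple(a.key for a in fr.atoms) != ref_keys:
                raise ValueError(
                    f"frame {i} has a different atom list than frame 1"
                )
        if self.window is None:
            self.window = (0, len(self.frames))
        start, end = self.window
        if not (0 <= start < end <= len(self.frames)):
            raise ValueError(f"invalid window {self.window} for "
                             f"{len(self.frames)} frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def m(self) -> int:
        """Number of windowed configurations."""
        start, end = self.window
        return end - start

    def windowed_frames(self, stride: int = 1) -> list:
        start, end = self.window
        return self.frames[start:end:stride]

    def windowed_coordinates(self, stride: int = 1) -> np.ndarray:
        """(m, n_atoms, 3) array over the analysis window."""
        return np.stack([f.coordinates for f in self.windowed_frames(stride)])


RegionPart = tuple  # (chain_id, (first_resnum, last_resnum), atom-name set or ALL)


@dataclass
class RegionSelection:
    """Fit-set and RMSD-set definitions.

    ``fit_region`` anchors the roto-translational least-squares fit (by
    default the backbone N/CA/C/O of the flanking framework segments);
    ``rmsd_region`` is where deviations are measured (typically every atom
    of the CDR loop, side chains included).  Residue ranges are inclusive on
    both ends, in author numbering.
    """

    fit_region: list
    rmsd_region: list

    def __post_init__(self):
        if not self.fit_region or not self.rmsd_region:
            raise ValueError("both fit and RMSD regions must be non-empty")
        self.fit_region = [_normalize_part(p, BACKBONE_ATOMS)
                           for p in self.fit_region]
        self.rmsd_region = [_normalize_part(p, ALL) for p in self.rmsd_region]
        fit_res = {(c, r) for c, rng, _ in self.fit_region
                   for r in range(rng[0], rng[1] + 1)}
        rmsd_res = {(c, r) for c, rng, _ in self.rmsd_region
                    for r in range(rng[0], rng[1] + 1)}
        overlap = fit_res & rmsd_res
        if overlap:
            warnings.warn(
                f"fit and RMSD regions overlap on residues {sorted(overlap)}",
                stacklevel=2,
            )


def _normalize_part(part, default_atoms) -> RegionPart:
    if len(part) == 2:
        chain, rng = part
        atoms = default_atoms
    else:
        chain, rng, atoms = part
    lo, hi = int(rng[0]), int(rng[1])
    if lo > hi:
        raise ValueError(f"residue range {rng} has first > last")
    if atoms != ALL:
        atoms = frozenset(str(a).strip() for a in atoms)
        if not atoms:
            raise ValueError("empty atom-name set in region part")
    return (str(chain), (lo, hi), atoms)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _keep_altloc(atom) -> bool:
    return atom.get_altloc() in (" ", "", "A")


def _model_to_frame(model) -> AtomFrame:
    records, xyz = [], []
    for chain in model:
        for residue in chain:
            het, resnum, icode = residue.get_id()
            for atom in residue.get_unpacked_list():
                if not _keep_altloc(atom):
                    continue
                records.append(AtomRecord(
                    chain_id=chain.get_id(),
                    residue_number=int(resnum),
                    residue_name=residue.get_resname().strip(),
                    atom_name=atom.get_name().strip(),
                    element=(atom.element or "").strip(),
                    insertion_code=icode.strip(),
                ))
                xyz.append(atom.get_coord())
    if not records:
        raise ValueError("model contains no atoms")
    coords_nm = np.asarray(xyz, dtype=float) * NM_PER_ANGSTROM
    return AtomFrame(tuple(records), coords_nm)


def read_multimodel_pdb(path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an Ensemble.

    One AtomFrame per MODEL record (a single-structure file yields one
    frame).  Coordinates are converted from Angstrom to nm.  All models must
    share an identical atom list; the first offending model is named in the
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises several parse-error types
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"{path} contains no models")
    frames = []
    ref_keys = None
    for model in models:
        frame = _model_to_frame(model)
        keys = tuple(a.key for a in frame.atoms)
        if ref_keys is None:
            ref_keys = keys
        elif keys != ref_keys:
            raise ValueError(
                f"model {model.get_id() + 1} of {path.name} has an "
                f"inconsistent atom set ({len(keys)} atoms vs "
                f"{len(ref_keys)} in model 1)"
            )
        frames.append(frame)
    return Ensemble(frames)


def _build_structure(frames: Iterable[AtomFrame], name="ensemble"):
    builder = StructureBuilder()
    builder.init_structure(name)
    for imodel, frame in enumerate(frames):
        builder.init_model(imodel)
        builder.init_seg("    ")
        current_chain, current_res = None, None
        serial = 1
        for rec, xyz in zip(frame.atoms, frame.coordinates):
            if rec.chain_id != current_chain:
                builder.init_chain(rec.chain_id)
                current_chain, current_res = rec.chain_id, None
            res_id = (" ", rec.residue_number, rec.insertion_code or " ")
            if res_id != current_res:
                builder.init_residue(rec.residue_name, *res_id)
                current_res = res_id
            builder.init_atom(
                rec.atom_name,
                np.asarray(xyz, dtype=float) / NM_PER_ANGSTROM,
                0.0, 1.0, " ", _pdb_atom_fullname(rec), serial,
                element=rec.element or None,
            )
            serial += 1
    return builder.get_structure()


def _pdb_atom_fullname(rec: AtomRecord) -> str:
    # Column alignment: 1-letter elements with short names start in column 14.
    name = rec.atom_name
    if len(name) < 4 and len(rec.element or name[:1]) == 1:
        return f" {name}"
    return name


def write_frame_pdb(frame: AtomFrame, path) -> Path:
    """Write a single conformation as a PDB file (nm -> Angstrom)."""
    return write_multimodel_pdb([frame], path)


def write_multimodel_pdb(frames: Sequence[AtomFrame], path) -> Path:
    frames = list(frames)
    if not frames or any(f.n_atoms == 0 for f in frames):
        raise ValueError("cannot write empty frame(s)")
    path = Path(path)
    io = PDBIO()
    io.set_structure(_build_structure(frames))
    io.save(str(path), write_end=True)
    return path


def write_ensemble_pdb(ens: Ensemble, path, windowed_only: bool = False) -> Path:
    frames = ens.windowed_frames() if windowed_only else ens.frames
    return write_multimodel_pdb(frames, path)


# ---------------------------------------------------------------------------
# Windowing and selections
# ---------------------------------------------------------------------------

def apply_window(ens: Ensemble, start_fraction: float) -> Ensemble:
    """Restrict analysis to the last ``1 - start_fraction`` of the frames.

    The early part of each trajectory is discarded to avoid bias from the
    shared starting structure (e.g. ``start_fraction=0.2`` analyses the last
    40 of 50 frames).  The start index is rounded down; stored frames are
    untouched.
    """
    if not (0.0 <= start_fraction <= 1.0):
        raise ValueError("start_fraction must be within [0, 1]")
    n = ens.n_frames
    start = int(start_fraction * n)
    if start >= n:
        raise ValueError(
            f"start_fraction {start_fraction} leaves no frames of {n}"
        )
    return Ensemble(ens.frames, frame_times=ens.frame_times, window=(start, n))


def select_atoms(frame: AtomFrame, region: list) -> np.ndarray:
    """Resolve one region (list of parts) to atom indices, in frame order.

    ``ALL`` parts expand to every atom of the matched residues, side chains
    included.  Raises if any part matches zero atoms.
    """
    region = [_normalize_part(p, ALL) for p in region]
    selected = np.zeros(frame.n_atoms, dtype=bool)
    for chain, (lo, hi), atoms in region:
        hit = False
        for i, rec in enumerate(frame.atoms):
            if rec.chain_id != chain or not (lo <= rec.residue_number <= hi):
                continue
            if atoms == ALL or rec.atom_name in atoms:
                selected[i] = True
                hit = True
        if not hit:
            raise ValueError(
                f"region part (chain {chain!r}, residues {lo}-{hi}) matches "
                f"no atoms in frame"
            )
    return np.nonzero(selected)[0]
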