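"""Ground-truth synthetic conformational ensembles and affinity tables.

Every pipeline stage (I/O, superposition, clustering, scoring, affinity
processing) is testable without MD trajectories or instrument data: the
generators here emulate a loop switching between a controllable number of
conformational basins, with controllable populations and per-atom Gaussian
noise, and emit the ground truth alongside each fixture.

The noise model is deliberately simple — isotropic per-coordinate Gaussian
jitter — because RMSD statistics under it are approximately known
analytically.  No physical realism (Ramachandran validity, force fields) is
attempted or needed for exercising the analysis machinery.

All generators take an explicit integer seed; there is no global random
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (ALL, AtomFrame, AtomRecord, BACKBONE_ATOMS,
                           Ensemble, RegionSelection)

_BACKBONE_NAMES = ("N", "CA", "C", "O")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _flank_length(n_residues: int) -> int:
    return max(1, n_residues // 3)


def default_region(n_residues: int) -> RegionSelection:
    """Region layout matching make_loop_reference.

    Two flanking "framework" segments anchor the fit (backbone atoms); the
    central "CDR" segment is the RMSD region (all atoms).
    """
    nf = _flank_length(n_residues)
    return RegionSelection(
        fit_region=[("H", (1, nf), BACKBONE_ATOMS),
                    ("H", (n_residues - nf + 1, n_residues), BACKBONE_ATOMS)],
        rmsd_region=[("H", (nf + 1, n_residues - nf), ALL)],
    )


def make_loop_reference(n_residues: int, seed: int) -> AtomFrame:
    """Deterministic idealized peptide-like heavy-atom frame.

    Residues 1..nf and (n-nf+1)..n are "framework" (backbone N/CA/C/O
    only); the central residues form the "CDR" and additionally carry a CB
    dummy side-chain atom.  Geometry is a gently curved backbone trace with
    a small seed-dependent perturbation; bit-identical for equal seeds.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues (two flanks + a loop)")
    rng = np.random.default_rng(seed)
    nf = _flank_length(n_residues)
    records, coords = [], []
    # local offsets of backbone atoms relative to the residue anchor (nm)
    offsets = {"N": np.array([-0.12, 0.04, 0.0]),
               "CA": np.array([0.0, 0.0, 0.0]),
               "C": np.array([0.13, 0.05, 0.02]),
               "O": np.array([0.15, 0.17, 0.02]),
               "CB": np.array([0.0, -0.10, 0.12])}
    for res in range(1, n_residues + 1):
        t = res - 1
        # curved trace: ~0.38 nm CA-CA spacing with a slow bend
        anchor = np.array([0.38 * t,
                           0.45 * np.sin(0.35 * t),
                           0.25 * np.cos(0.22 * t)])
        in_cdr = nf < res <= n_residues - nf
        names = _BACKBONE_NAMES + (("CB",) if in_cdr else ())
        resname = "ALA" if in_cdr else "GLY"
        for name in names:
            records.append(AtomRecord(chain_id="H", residue_number=res,
                                      residue_name=resname, atom_name=name,
                                      element=_ELEMENT[name]))
            coords.append(anchor + offsets[name])
    coords = np.asarray(coords)
    coords += rng.normal(scale=0.01, size=coords.shape)  # break symmetry
    return AtomFrame(tuple(records), coords)


def make_basin_frames(reference: AtomFrame, region: RegionSelection,
                      n_basins: int, separation: float, seed: int) -> list:
    """Basin center conformations with exact pairwise CDR RMSD.

    Each basin displaces the RMSD-region atoms by a field chosen so that
    the pairwise RMSD between any two basin centers equals ``separation``
    (the fields are scaled orthonormal directions in conformation space);
    framework atoms are untouched, so the inter-basin RMSD survives the
    framework fit exactly.
    """
    if n_basins < 1:
        raise ValueError("need at least one basin")
    from .structure_io import select_atoms
    idx = select_atoms(reference, region.rmsd_region)
    k = idx.size
    rng = np.random.default_rng(seed)
    # orthonormal displacement fields in R^{3k}
    raw = rng.normal(size=(3 * k, n_basins))
    q, _ = np.linalg.qr(raw)
    fields = q.T.reshape(n_basins, k, 3)
    # |u_i - u_j| = sqrt(2) for orthonormal fields; RMSD = |u_i-u_j|/sqrt(k)
    scale = separation * np.sqrt(k) / np.sqrt(2.0)
    frames = []
    for b in range(n_basins):
        xyz = reference.coordinates.copy()
        xyz[idx] += scale * fields[b]
        frames.append(AtomFrame(reference.atoms, xyz))
    return frames


@dataclass
class BasinSpec:
    """Generative model for a multi-basin loop ensemble."""

    basin_frames: list              # one AtomFrame per basin, same atom set
    weights: tuple                  # basin populations, sum to 1
    region: RegionSelection
    jitter_sigma: float = 0.0       # nm, per-coordinate, RMSD-region atoms
    frame_jitter_sigma: float = 0.0  # nm, per-coordinate, fit-region atoms
    rigid_motion: bool = False      # random global rotation+translation
    seed: int = 0

    def __post_init__(self):
        if not self.basin_frames:
            raise ValueError("need at least one basin frame")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.basin_frames),):
            raise ValueError("one weight per basin required")
        if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = tuple(w)
        if self.jitter_sigma < 0 or self.frame_jitter_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")


def sample_ensemble(spec: BasinSpec, m: int, s: int = 1):
    """Draw ``s`` replicate ensembles of ``m`` frames each.

    Per frame: a basin is drawn by weight, Gaussian jitter is added
    (``jitter_sigma`` on RMSD-region atoms, ``frame_jitter_sigma`` on
    fit-region atoms) and, if requested, a random global rigid motion is
    applied.  Returns ``(ensembles, labels)`` where ``labels`` is an (s, m)
    integer array of ground-truth basin indices.
    """
    if m < 1 or s < 1:
        raise ValueError("m and s must be >= 1")
    from .structure_io import select_atoms
    rng = np.random.default_rng(spec.seed)
    template = spec.basin_frames[0]
    rmsd_idx = select_atoms(template, spec.region.rmsd_region)
    fit_idx = select_atoms(template, spec.region.fit_region)
    weights = np.asarray(spec.weights)
    ensembles, labels = [], np.empty((s, m), dtype=int)
    for j in range(s):
        frames = []
        for x in range(m):
            b = int(rng.choice(len(weights), p=weights))
            labels[j, x] = b
            xyz = spec.basin_frames[b].coordinates.copy()
            if spec.jitter_sigma > 0:
                xyz[rmsd_idx] += rng.normal(scale=spec.jitter_sigma,
                                            size=(rmsd_idx.size, 3))
            if spec.frame_jitter_sigma > 0:
                xyz[fit_idx] += rng.normal(scale=spec.frame_jitter_sigma,
                                           size=(fit_idx.size, 3))
            if spec.rigid_motion:
                rot = Rotation.random(random_state=rng).as_matrix()
                trans = rng.uniform(-1.0, 1.0, size=3)
                xyz = xyz @ rot.T + trans
            frames.append(AtomFrame(template.atoms, xyz))
        ensembles.append(Ensemble(frames))
    return ensembles, labels


def make_affinity_fixture(n_variants: int, seed: int,
                          n_good: int = 5,
                          dg_noise: float = 1.0,
                          n_low_r2: int = 1,
                          n_outliers: int = 1,
                          outlier_shift: float = 15.0,
                          temperature: float = 293.0):
    """Synthetic affinity table with planted bad records and known truth.

    Per variant: ``n_good`` measurements whose dG scatters around a true
    value (sd ``dg_noise`` kJ/mol, i.e. log-normal K_d), plus ``n_low_r2``
    records with R^2 <= 0.8 and ``n_outliers`` records displaced by
    ``outlier_shift`` kJ/mol from the truth.  Returns
    ``(records, truth)`` where truth maps variant id to a dict with the
    true mean dG and the measurement ids of the planted records.
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    from .affinity import AffinityRecord, K_B
    rng = np.random.default_rng(seed)
    kbt = K_B * temperature

    def kd_from_dg(dg):
        return float(np.exp(dg / kbt))

    records, truth = [], {}
    for v in range(n_variants):
        vid = f"VAR{v + 1:02d}"
        true_dg = float(rng.uniform(-55.0, -35.0))
        planted_r2, planted_out = [], []
        k = 0
        for _ in range(n_good):
            k += 1
            mid = f"{vid}.m{k}"
            dg = true_dg + float(rng.normal(scale=dg_noise))
            records.append(AffinityRecord(
                variant_id=vid, kd=kd_from_dg(dg),
                fit_r2=float(rng.uniform(0.9, 1.0)),
                temperature=temperature, measurement_id=mid))
        for q in range(n_low_r2):
            k += 1
            mid = f"{vid}.m{k}"
            planted_r2.append(mid)
            dg = true_dg + float(rng.normal(scale=dg_noise))
            # first planted record sits exactly on the R^2 = 0.8 boundary,
            # which must be excluded ("below or equal to" rule)
            r2 = 0.8 if q == 0 else float(rng.uniform(0.3, 0.75))
            records.append(AffinityRecord(
                variant_id=vid, kd=kd_from_dg(dg), fit_r2=r2,
                temperature=temperature, measurement_id=mid))
        for _ in range(n_outliers):
            k += 1
            mid = f"{vid}.m{k}"
            planted_out.append(mid)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            records.append(AffinityRecord(
                variant_id=vid, kd=kd_from_dg(true_dg + sign * outlier_shift),
                fit_r2=float(rng.uniform(0.9, 1.0)),
                temperature=temperature, measurement_id=mid))
        truth[vid] = {"true_dg": true_dg,
                      "se": dg_noise / np.sqrt(n_good),
                      "planted_low_r2": planted_r2,
                      "planted_outliers": planted_out}
    return records, truth


def write_affinity_table(records, path) -> Path:
    """Write records in the delimited format the affinity reader expects."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("variant,kd,kd_unit,r2,temperature_K,measurement_id\n")
        for r in records:
            kd = "ND" if r.kd is None else f"{r.kd:.6e}"
            fh.write(f"{r.variant_id},{kd},M,{r.fit_r2:.4f},"
                     f"{r.temperature:.1f},{r.measurement_id}\n")
    return path
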