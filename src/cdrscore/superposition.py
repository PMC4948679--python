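"""Roto-translational least-squares fitting and RMSD.

The fit minimizes the sum of squared deviations over the *fit* atoms
(typically framework backbone) and is then applied to the whole frame; RMSD
is evaluated over a possibly different *RMSD* set (typically all CDR atoms).
The optimal rotation is the closed-form Kabsch solution with the reflection
branch forbidden (determinant forced to +1).  Fits are unweighted by
default; mass weighting is available via ``weights``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomFrame, Ensemble, RegionSelection, select_atoms

_DEGENERATE_TOL = 1e-10


@dataclass
class FitResult:
    rotation: np.ndarray     # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), nm
    fit_rmsd: float          # nm, over fit atoms after the fit


def kabsch_batch(mobile: np.ndarray, reference: np.ndarray,
                 weights: np.ndarray | None = None):
    """Optimal proper rotations/translations for batches of point sets.

    Parameters
    ----------
    mobile, reference : (..., K, 3) arrays
        Paired point sets; the rotation maps centered mobile points onto
        centered reference points.
    weights : (K,) array, optional
        Per-point fit weights (e.g. masses); uniform if omitted.

    Returns
    -------
    R : (..., 3, 3), t : (..., 3), rmsd : (...)
        ``x -> x @ R.T + t`` superposes mobile onto reference; ``rmsd`` is
        the (weighted) RMSD over the fit points after superposition.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[-1] != 3:
        raise ValueError("mobile/reference must have matching (..., K, 3) shapes")
    k = mobile.shape[-2]
    if k < 3:
        raise ValueError("at least 3 fit atoms are required")
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    wcol = w[:, None]

    mob_c = (mobile * wcol).sum(axis=-2, keepdims=True)
    ref_c = (reference * wcol).sum(axis=-2, keepdims=True)
    a = mobile - mob_c
    b = reference - ref_c

    # covariance H = a^T W b per batch element
    h = np.einsum("...ki,k,...kj->...ij", a, w, b)
    u, s, vt = np.linalg.svd(h)
    # forbid reflections: flip the smallest singular direction if det < 0
    det = np.linalg.det(np.einsum("...ij,...jk->...ik",
                                  np.swapaxes(vt, -1, -2),
                                  np.swapaxes(u, -1, -2)))
    signs = np.ones(h.shape[:-2] + (3,))
    signs[..., -1] = np.sign(det)
    r = np.einsum("...ji,...j,...kj->...ik", vt, signs, u)

    # degenerate geometry: fewer than 2 significant singular values means
    # the reference fit points are collinear/coincident -> no unique rotation
    scale = np.maximum(s[..., 0], _DEGENERATE_TOL)
    if np.any(s[..., 1] / scale < _DEGENERATE_TOL):
        raise ValueError("degenerate (collinear or coincident) fit geometry")

    t = ref_c[..., 0, :] - np.einsum("...ij,...j->...i", r, mob_c[..., 0, :])
    fitted = np.einsum("...ij,...kj->...ki", r, mobile) + t[..., None, :]
    d2 = ((fitted - reference) ** 2).sum(axis=-1)
    rmsd = np.sqrt((d2 * w).sum(axis=-1))
    return r, t, rmsd


def superpose(mobile: AtomFrame, reference: AtomFrame,
              fit_indices_mobile, fit_indices_reference,
              weights: np.ndarray | None = None):
    """Superpose ``mobile`` onto ``reference`` on the given fit atoms.

    Returns ``(FitResult, transformed_frame)``; the rigid transform is
    applied to *all* atoms of the mobile frame.
    """
    im = np.asarray(fit_indices_mobile, dtype=int)
    ir = np.asarray(fit_indices_reference, dtype=int)
    if im.shape != ir.shape:
        raise ValueError("fit index lists must have equal length")
    r, t, rmsd = kabsch_batch(mobile.coordinates[im],
                              reference.coordinates[ir], weights=weights)
    fit = FitResult(rotation=r, translation=t, fit_rmsd=float(rmsd))
    return fit, mobile.transformed(r, t)


def region_rmsd(frame_a: AtomFrame, frame_b: AtomFrame,
                rmsd_indices_a, rmsd_indices_b) -> float:
    """Plain (unweighted) RMSD over paired atoms of two fitted frames."""
    ia = np.asarray(rmsd_indices_a, dtype=int)
    ib = np.asarray(rmsd_indices_b, dtype=int)
    if ia.shape != ib.shape or ia.size == 0:
        raise ValueError("RMSD index lists must be non-empty and equal length")
    d2 = ((frame_a.coordinates[ia] - frame_b.coordinates[ib]) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def fit_rmsd_batch(mobile_coords: np.ndarray, reference_coords: np.ndarray,
                   fit_idx_mobile, fit_idx_ref,
                   rmsd_idx_mobile, rmsd_idx_ref) -> np.ndarray:
    """Fit many mobile frames onto reference frame(s), RMSD on another set.

    ``mobile_coords`` is (F, N, 3); ``reference_coords`` is (N', 3) or
    (F, N', 3) for per-frame references.  Returns (F,) RMSD values in nm.
    """
    mobile_coords = np.asarray(mobile_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    fm = mobile_coords[:, fit_idx_mobile, :]
    rm = mobile_coords[:, rmsd_idx_mobile, :]
    if reference_coords.ndim == 2:
        fr = np.broadcast_to(reference_coords[fit_idx_ref],
                             fm.shape)
        rr = np.broadcast_to(reference_coords[rmsd_idx_ref], rm.shape)
    else:
        fr = reference_coords[:, fit_idx_ref, :]
        rr = reference_coords[:, rmsd_idx_ref, :]
    r, t, _ = kabsch_batch(fm, fr)
    fitted = np.einsum("fij,fkj->fki", r, rm) + t[:, None, :]
    d2 = ((fitted - rr) ** 2).sum(axis=-1)
    return np.sqrt(d2.mean(axis=-1))


def rmsd_timeseries(ens: Ensemble, reference: AtomFrame,
                    region: RegionSelection, stride: int = 1):
    """Per-frame RMSD of the windowed ensemble to a reference structure.

    Each frame is independently fitted to the reference on the fit region,
    then the RMSD is evaluated on the RMSD region.  Returns a list of
    ``(frame_index, rmsd_nm)`` over the analysis window.
    """
    fit_e = select_atoms(ens.frames[0], region.fit_region)
    rmsd_e = select_atoms(ens.frames[0], region.rmsd_region)
    fit_r = select_atoms(reference, region.fit_region)
    rmsd_r = select_atoms(reference, region.rmsd_region)
    if fit_e.size != fit_r.size:
        raise ValueError("fit region resolves to different atom counts on "
                         "ensemble and reference")
    if rmsd_e.size != rmsd_r.size:
        raise ValueError("RMSD region resolves to different atom counts on "
                         "ensemble and reference")
    coords = ens.windowed_coordinates(stride)
    values = fit_rmsd_batch(coords, reference.coordinates,
                            fit_e, fit_r, rmsd_e, rmsd_r)
    start, end = ens.window
    indices = range(start, end, stride)
    return [(i, float(v)) for i, v in zip(indices, values)]


def write_timeseries(series, path) -> None:
    """Persist a (frame, rmsd_nm) series as delimited text with a header."""
    with open(path, "w") as fh:
        fh.write("frame\trmsd_nm\n")
        for i, v in series:
            fh.write(f"{i}\t{v:.6f}\n")
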