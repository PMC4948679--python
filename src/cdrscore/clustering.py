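"""Cross-RMSD matrix and neighbor-count (Daura) conformational clustering.

Frames pooled from all wild-type replicates are compared pairwise: each
pair is superposed on the framework fit region and the RMSD is measured on
the CDR region.  The greedy neighbor-count algorithm then extracts
clusters: the frame with the most neighbors within the cutoff becomes the
central member structure (CMS) of the next cluster, it and its neighbors
are removed, and the procedure repeats until every frame is assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import (AtomFrame, Ensemble, RegionSelection, select_atoms,
                           write_frame_pdb)
from .superposition import kabsch_batch

_PAIR_CHUNK = 200_000  # pair fits per vectorized batch; bounds peak memory


@dataclass
class DistanceMatrix:
    """Symmetric pairwise RMSD matrix over pooled frames, in nm."""

    values: np.ndarray                 # (N, N)
    frame_provenance: list             # [(replicate index, frame index), ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12) or np.any(v < -1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v
        if len(self.frame_provenance) != v.shape[0]:
            raise ValueError("provenance length must match matrix size")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusteringParams:
    cutoff: float = 0.2                  # nm
    significance_threshold: float = 0.20  # population fraction
    max_clusters: int | None = None

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (0 < self.significance_threshold <= 1):
            raise ValueError("significance_threshold must be in (0, 1]")


@dataclass
class ClusterResult:
    assignments: np.ndarray      # frame -> 1-based cluster id, extraction order
    cms_indices: dict            # cluster id -> pooled frame index of the CMS
    populations: dict            # cluster id -> fraction of pooled frames
    significant_ids: list = field(default_factory=list)
    neighbor_counts: dict = field(default_factory=dict)  # cluster id -> count

    @property
    def n_clusters(self) -> int:
        return len(self.cms_indices)

    @property
    def a(self) -> int:
        """Number of significant clusters (the score's cluster count)."""
        return len(self.significant_ids)


def cross_rmsd_matrix(ensembles, region: RegionSelection,
                      stride: int = 1) -> DistanceMatrix:
    """Pairwise fitted RMSD over frames pooled from all replicates.

    Every pair is superposed on the fit region (framework backbone) and the
    RMSD evaluated on the RMSD region (CDR atoms).  Because fit and RMSD
    sets differ, the two fit directions differ slightly; the matrix is
    symmetrized by averaging them.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    template = ensembles[0].frames[0]
    fit_idx = select_atoms(template, region.fit_region)
    rmsd_idx = select_atoms(template, region.rmsd_region)

    coords, provenance = [], []
    for rep, ens in enumerate(ensembles):
        start, end = ens.window
        for fi in range(start, end, stride):
            coords.append(ens.frames[fi].coordinates)
            provenance.append((rep, fi))
    n = len(coords)
    if n < 2:
        raise ValueError("fewer than 2 pooled frames")
    coords = np.stack(coords)
    fitc = coords[:, fit_idx, :]
    rmsdc = coords[:, rmsd_idx, :]

    iu, ju = np.triu_indices(n, k=1)
    dm = np.zeros((n, n))
    for lo in range(0, iu.size, _PAIR_CHUNK):
        sl = slice(lo, lo + _PAIR_CHUNK)
        i, j = iu[sl], ju[sl]
        d_ij = _fitted_pair_rmsd(fitc[j], fitc[i], rmsdc[j], rmsdc[i])
        d_ji = _fitted_pair_rmsd(fitc[i], fitc[j], rmsdc[i], rmsdc[j])
        d = 0.5 * (d_ij + d_ji)
        dm[i, j] = d
        dm[j, i] = d
    return DistanceMatrix(dm, provenance)


def _fitted_pair_rmsd(fit_mob, fit_ref, rmsd_mob, rmsd_ref):
    r, t, _ = kabsch_batch(fit_mob, fit_ref)
    fitted = np.einsum("pij,pkj->pki", r, rmsd_mob) + t[:, None, :]
    return np.sqrt(((fitted - rmsd_ref) ** 2).sum(axis=-1).mean(axis=-1))


def daura_cluster(dm: DistanceMatrix, params: ClusteringParams) -> ClusterResult:
    """Greedy neighbor-count clustering at a fixed RMSD cutoff.

    A frame counts as its own neighbor.  Ties in neighbor count are broken
    by the lowest pooled frame index (deterministic).  Extraction order is
    non-increasing in cluster size.
    """
    n = dm.size
    adjacency = dm.values <= params.cutoff
    np.fill_diagonal(adjacency, True)
    unassigned = np.ones(n, dtype=bool)
    assignments = np.zeros(n, dtype=int)
    cms_indices, populations, counts = {}, {}, {}
    cluster_id = 0
    while unassigned.any():
        live = adjacency & unassigned[None, :] & unassigned[:, None]
        neighbor_counts = live.sum(axis=1)
        neighbor_counts[~unassigned] = -1
        center = int(np.argmax(neighbor_counts))  # argmax -> lowest index tie-break
        if (params.max_clusters is not None
                and cluster_id == params.max_clusters - 1):
            # last allowed cluster absorbs every remaining frame
            members = np.nonzero(unassigned)[0]
        else:
            members = np.nonzero(live[center])[0]
        cluster_id += 1
        assignments[members] = cluster_id
        cms_indices[cluster_id] = center
        populations[cluster_id] = len(members) / n
        counts[cluster_id] = int(neighbor_counts[center])
        unassigned[members] = False
    return ClusterResult(assignments=assignments, cms_indices=cms_indices,
                         populations=populations, neighbor_counts=counts)


def significant_clusters(cr: ClusterResult,
                         params: ClusteringParams) -> ClusterResult:
    """Mark clusters whose population reaches the significance threshold.

    At least one cluster is always retained: if no population reaches the
    threshold, cluster 1 (the largest) is kept with a warning.
    """
    ids = [cid for cid in sorted(cr.cms_indices)
           if cr.populations[cid] >= params.significance_threshold]
    if not ids:
        warnings.warn(
            "no cluster reaches the significance threshold "
            f"{params.significance_threshold}; keeping cluster 1 "
            f"(population {cr.populations.get(1, 0.0):.3f})",
            stacklevel=2,
        )
        ids = [1]
    cr.significant_ids = ids
    return cr


def pooled_frame(ensembles, dm: DistanceMatrix, pooled_index: int) -> AtomFrame:
    rep, fi = dm.frame_provenance[pooled_index]
    return ensembles[rep].frames[fi]


def cms_frames(cr: ClusterResult, ensembles, dm: DistanceMatrix):
    """(cluster id, AtomFrame) pairs for the significant clusters."""
    if not cr.significant_ids:
        raise ValueError("significant_ids not populated; run "
                         "significant_clusters first")
    return [(cid, pooled_frame(ensembles, dm, cr.cms_indices[cid]))
            for cid in cr.significant_ids]


def export_cms(cr: ClusterResult, ensembles, dm: DistanceMatrix,
               out_dir) -> list:
    """Write one PDB per significant central member structure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cid, frame in cms_frames(cr, ensembles, dm):
        path = out_dir / f"cms_cluster{cid}.pdb"
        write_frame_pdb(frame, path)
        paths.append(path)
    return paths


def save_distance_matrix(dm: DistanceMatrix, path, provenance_path=None) -> None:
    """Persist the matrix as delimited text plus a provenance sidecar."""
    np.savetxt(path, dm.values, fmt="%.6f", delimiter="\t")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            fh.write("pooled_index\treplicate\tframe\n")
            for k, (rep, fi) in enumerate(dm.frame_provenance):
                fh.write(f"{k}\t{rep}\t{fi}\n")


def load_distance_matrix(path, provenance_path=None) -> DistanceMatrix:
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if provenance_path is not None:
        prov = []
        with open(provenance_path) as fh:
            next(fh)
            for line in fh:
                _, rep, fi = line.split()
                prov.append((int(rep), int(fi)))
    else:
        prov = [(0, i) for i in range(values.shape[0])]
    return DistanceMatrix(values, prov)
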