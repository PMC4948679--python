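"""Multi-threshold ensemble-similarity score and binder/non-binder cutoff.

The score of a variant measures how often its CDR conformations fall within
a set of RMSD thresholds of the wild-type central member structures (CMS),
after fitting each configuration onto each CMS on the framework backbone:

    score = 100 / (s * m * a) * sum_i sum_j sum_k sum_x [RMSD_(x,CMS_i) <= c_k]

where ``c`` is the strictly increasing threshold vector (nm), ``n = |c|``,
``a`` the number of significant wild-type clusters, ``s`` the number of
replicate simulations of the variant and ``m`` the number of analysed
configurations per replicate.  The normalization divides by ``s*m*a`` but
*not* by ``n``, so a perfect ensemble scores ``100*n``; an optional
``score/n`` column is provided for convenience.  Replicates of unequal
length are each normalized by their own ``m_j``, which reduces exactly to
the formula above when all ``m_j`` are equal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomFrame, RegionSelection, select_atoms
from .superposition import fit_rmsd_batch


@dataclass
class ScoreSpec:
    """Fixed wild-type reference against which every variant is scored."""

    thresholds: tuple            # c, strictly increasing, nm
    cms_set: list                # [(cluster id, AtomFrame), ...] — a entries
    region: RegionSelection

    def __post_init__(self):
        c = tuple(float(x) for x in self.thresholds)
        if not c or any(x <= 0 for x in c):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = c
        if not self.cms_set:
            raise ValueError("at least one CMS is required")

    @property
    def n(self) -> int:
        return len(self.thresholds)

    @property
    def a(self) -> int:
        return len(self.cms_set)


@dataclass
class ScoreResult:
    variant_id: str
    score: float                       # 0 .. 100*n
    per_replicate: list                # per-replicate partial scores
    per_threshold_counts: dict         # (cms id, replicate, threshold idx) -> count
    m_per_replicate: list
    s: int
    a: int
    n: int

    @property
    def score_per_threshold(self) -> float:
        """Score normalized by the threshold count (0..100 scale)."""
        return self.score / self.n


@dataclass
class CutoffModel:
    cutoff: float
    training_pairs: list               # (variant id, score, binder flag)
    inconsistencies: list = field(default_factory=list)


def _cdr_atom_identity(frame: AtomFrame, region: RegionSelection):
    idx = select_atoms(frame, region.rmsd_region)
    return tuple(frame.atoms[i].key for i in idx), idx


def _resolve_rmsd_indices(ens_frame: AtomFrame, cms: AtomFrame,
                          region: RegionSelection, cdr_mutant: bool):
    """Map RMSD-region atoms between a variant frame and a wild-type CMS.

    The CDR is held constant across variants by construction, so the atom
    sets must match exactly; a variant flagged as CDR-mutant instead falls
    back to the shared atoms, with a warning.
    """
    keys_e, idx_e = _cdr_atom_identity(ens_frame, region)
    keys_c, idx_c = _cdr_atom_identity(cms, region)
    if keys_e == keys_c:
        return idx_e, idx_c
    if not cdr_mutant:
        only_e = set(keys_e) - set(keys_c)
        only_c = set(keys_c) - set(keys_e)
        raise ValueError(
            "CDR (RMSD-region) atom sets differ between variant and CMS "
            f"(variant-only: {sorted(only_e)[:5]}, CMS-only: "
            f"{sorted(only_c)[:5]}); the CDR is expected to be conserved — "
            "pass cdr_mutant=True to fall back to shared atoms"
        )
    shared = [k for k in keys_e if k in set(keys_c)]
    if not shared:
        raise ValueError("no shared CDR atoms between variant and CMS")
    warnings.warn(
        f"CDR-mutant variant: RMSD restricted to {len(shared)} shared atoms "
        f"(variant has {len(keys_e)}, CMS has {len(keys_c)})",
        stacklevel=3,
    )
    pos_e = {k: i for k, i in zip(keys_e, idx_e)}
    pos_c = {k: i for k, i in zip(keys_c, idx_c)}
    return (np.array([pos_e[k] for k in shared]),
            np.array([pos_c[k] for k in shared]))


def score_variant(ensembles, spec: ScoreSpec, variant_id: str = "variant",
                  stride: int = 1, cdr_mutant: bool = False) -> ScoreResult:
    """Similarity score of one variant's replicate ensembles to the CMS set.

    For every replicate, every windowed configuration is fitted onto every
    CMS on the fit region; the RMSD over the RMSD region is compared to each
    threshold and the indicator counts are accumulated.
    """
    if not ensembles:
        raise ValueError("need at least one replicate ensemble")
    c = np.asarray(spec.thresholds)
    s = len(ensembles)
    a = spec.a
    counts = {}
    per_replicate = []
    m_per_replicate = []
    for j, ens in enumerate(ensembles):
        m_j = len(range(*ens.window, stride))
        if m_j == 0:
            raise ValueError(f"replicate {j} has zero windowed frames")
        m_per_replicate.append(m_j)
        coords = ens.windowed_coordinates(stride)
        fit_e = select_atoms(ens.frames[0], spec.region.fit_region)
        rep_total = 0
        for cid, cms in spec.cms_set:
            fit_c = select_atoms(cms, spec.region.fit_region)
            if fit_e.size != fit_c.size:
                raise ValueError(
                    "fit region resolves to different atom counts on "
                    f"variant ({fit_e.size}) and CMS {cid} ({fit_c.size})"
                )
            ridx_e, ridx_c = _resolve_rmsd_indices(ens.frames[0], cms,
                                                   spec.region, cdr_mutant)
            rmsd = fit_rmsd_batch(coords, cms.coordinates,
                                  fit_e, fit_c, ridx_e, ridx_c)
            for k, ck in enumerate(c):
                cnt = int((rmsd <= ck).sum())
                counts[(cid, j, k)] = cnt
                rep_total += cnt
        per_replicate.append(100.0 * rep_total / (m_j * a))
    score = sum(per_replicate) / s
    return ScoreResult(variant_id=variant_id, score=float(score),
                       per_replicate=per_replicate,
                       per_threshold_counts=counts,
                       m_per_replicate=m_per_replicate, s=s, a=a, n=spec.n)


def score_panel(variant_ensembles: dict, spec: ScoreSpec, stride: int = 1,
                cdr_mutants=()) -> list:
    """Score every variant of a panel against the same wild-type reference."""
    if not variant_ensembles:
        raise ValueError("empty variant panel")
    return [score_variant(ens_list, spec, variant_id=vid, stride=stride,
                          cdr_mutant=vid in set(cdr_mutants))
            for vid, ens_list in variant_ensembles.items()]


def fit_cutoff(training) -> CutoffModel:
    """Estimate the score cutoff separating binders from non-binders.

    If the classes separate, the cutoff is the midpoint between the highest
    non-binder score and the lowest binder score.  Otherwise the cutoff
    minimizing misclassifications is chosen (ties broken toward the lower
    cutoff) and the violating variants are reported in ``inconsistencies``.
    A variant is predicted to bind iff its score is strictly above the
    cutoff.
    """
    training = list(training)
    binders = [(v, x) for v, x, b in training if b]
    non_binders = [(v, x) for v, x, b in training if not b]
    if not binders or not non_binders:
        raise ValueError("training set needs at least one binder and one "
                         "non-binder")
    lo_b = min(x for _, x in binders)
    hi_nb = max(x for _, x in non_binders)
    if hi_nb < lo_b:
        return CutoffModel(cutoff=0.5 * (hi_nb + lo_b),
                           training_pairs=training)

    scores = sorted({x for _, x, _ in training})
    best_cut, best_err, best_bad = None, None, None
    for cut in scores:  # ascending -> first minimum is the lowest cutoff
        bad = [v for v, x, b in training if (x > cut) != b]
        if best_err is None or len(bad) < best_err:
            best_cut, best_err, best_bad = cut, len(bad), bad
    return CutoffModel(cutoff=float(best_cut), training_pairs=training,
                       inconsistencies=best_bad)


def classify(scores, model: CutoffModel):
    """Predict binder status: score strictly above the cutoff binds.

    Scores exactly at the cutoff are classified non-binder (conservative
    for immunogenicity-driven design).  Input order is preserved.
    """
    return [(sr.variant_id, sr.score > model.cutoff) for sr in scores]


def write_score_report(results, path) -> None:
    """Delimited-text score report: one row per variant."""
    with open(path, "w") as fh:
        fh.write("variant\tscore\tscore_per_threshold\ts\tm\ta\tn\n")
        for r in results:
            m_repr = ",".join(str(m) for m in r.m_per_replicate)
            fh.write(f"{r.variant_id}\t{r.score:.4f}\t"
                     f"{r.score_per_threshold:.4f}\t{r.s}\t{m_repr}\t"
                     f"{r.a}\t{r.n}\n")
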