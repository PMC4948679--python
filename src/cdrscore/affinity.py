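"""Binding free energies from dissociation constants, with outlier control.

Experimental K_d values (from e.g. bio-layer interferometry fits) are
converted to binding free energies against a 1 M standard state,

    dG = k_B * T * ln(K_d),

after discarding measurements whose sensorgram fit quality is poor
(R^2 <= 0.8).  Measurements deviating by more than 5.6 kJ/mol from the
running average — the free-energy equivalent of a tenfold change in K_d at
293 K — are excluded iteratively, one at a time.  A variant's estimate is
only reported when at least three measurements survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Boltzmann constant in kJ/(mol K) (i.e. the molar gas constant R).
K_B = 0.0083145

DEFAULT_TEMPERATURE = 293.0    # K
DEFAULT_R2_THRESHOLD = 0.8
DEFAULT_OUTLIER_WINDOW = 5.6   # kJ/mol, = k_B * 293 K * ln 10 to one decimal
MIN_MEASUREMENTS = 3

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
                 "pM": 1e-12}


@dataclass
class AffinityRecord:
    variant_id: str
    kd: float | None               # molar; None = below detection limit
    fit_r2: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    measurement_id: str = ""

    def __post_init__(self):
        if self.kd is not None and self.kd <= 0:
            raise ValueError("K_d must be positive (or None if undetectable)")
        if not (0.0 <= self.fit_r2 <= 1.0):
            raise ValueError("fit R^2 must lie in [0, 1]")

    @property
    def detectable(self) -> bool:
        return self.kd is not None


@dataclass
class BindingEstimate:
    variant_id: str
    mean_dG: float | None            # kJ/mol; None if not estimable
    n_used: int
    excluded: list = field(default_factory=list)  # (record, reason)
    sufficient: bool = True
    below_detection: bool = False

    @property
    def valid(self) -> bool:
        return self.sufficient and not self.below_detection


def delta_g(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy k_B*T*ln(K_d) in kJ/mol (K_d in M, T in K)."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("K_d and temperature must be positive")
    return K_B * temperature * math.log(kd)


def filter_r2(records, threshold: float = DEFAULT_R2_THRESHOLD):
    """Drop measurements with fit R^2 below *or equal to* the threshold."""
    kept, excluded = [], []
    for rec in records:
        if rec.fit_r2 <= threshold:
            excluded.append((rec, "low_r2"))
        else:
            kept.append(rec)
    return kept, excluded


def iterative_outlier_exclusion(values, window: float = DEFAULT_OUTLIER_WINDOW):
    """One-at-a-time exclusion of values far from the running mean.

    Repeatedly: compute the mean of the current set; if any value deviates
    by more than ``window``, remove the single largest deviator (ties go to
    the earliest in input order) and recompute.  Stops when nothing deviates
    or fewer than two values remain.  Returns (kept_indices, excluded_indices)
    into the input list, preserving input order.
    """
    values = [float(v) for v in values]
    if not values:
        raise ValueError("need at least one value")
    alive = list(range(len(values)))
    excluded = []
    while len(alive) >= 2:
        mean = sum(values[i] for i in alive) / len(alive)
        devs = [abs(values[i] - mean) for i in alive]
        worst = max(devs)
        if worst <= window:
            break
        drop = alive[devs.index(worst)]  # first occurrence -> input order
        alive.remove(drop)
        excluded.append(drop)
    return alive, excluded


def estimate_binding(records, r2_threshold: float = DEFAULT_R2_THRESHOLD,
                     window: float = DEFAULT_OUTLIER_WINDOW,
                     min_measurements: int = MIN_MEASUREMENTS) -> BindingEstimate:
    """Full per-variant pipeline: R^2 filter -> dG -> outlier loop -> mean.

    Fewer than ``min_measurements`` survivors yields an insufficient-data
    estimate (``sufficient=False``) rather than a silent mean.  A variant
    whose detectable measurements are all censored (K_d below the detection
    limit) is flagged ``below_detection``.
    """
    records = list(records)
    if not records:
        raise ValueError("no affinity records given")
    variant_id = records[0].variant_id
    if any(r.variant_id != variant_id for r in records):
        raise ValueError("records belong to more than one variant")

    detectable = [r for r in records if r.detectable]
    if not detectable:
        return BindingEstimate(variant_id=variant_id, mean_dG=None, n_used=0,
                               excluded=[], sufficient=False,
                               below_detection=True)

    kept, excluded = filter_r2(detectable, r2_threshold)
    dgs = [delta_g(r.kd, r.temperature) for r in kept]
    if dgs:
        alive, dropped = iterative_outlier_exclusion(dgs, window)
        excluded += [(kept[i], "outlier") for i in dropped]
        survivors = [dgs[i] for i in alive]
    else:
        survivors = []
    n_used = len(survivors)
    mean = float(np.mean(survivors)) if survivors else None
    return BindingEstimate(variant_id=variant_id, mean_dG=mean, n_used=n_used,
                           excluded=excluded,
                           sufficient=n_used >= min_measurements)


# ---------------------------------------------------------------------------
# Table I/O and training-table construction
# ---------------------------------------------------------------------------

def read_affinity_table(path) -> list:
    """Read a delimited affinity table into AffinityRecords.

    Expected header: ``variant,kd,kd_unit,r2,temperature_K`` (comma or tab
    separated).  ``kd`` must carry an explicit unit (M, mM, uM/µM, nM, pM);
    an empty or ``ND`` kd marks a below-detection measurement.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant", "kd", "kd_unit", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity table misses columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        raw = row["kd"]
        if pd.isna(raw) or str(raw).strip().upper() in ("", "ND", "NA"):
            kd = None
        else:
            unit = str(row["kd_unit"]).strip()
            if unit not in _UNIT_FACTORS:
                raise ValueError(
                    f"row {i}: unknown K_d unit {unit!r} (use one of "
                    f"{sorted(_UNIT_FACTORS)})"
                )
            kd = float(raw) * _UNIT_FACTORS[unit]
        temp = float(row.get("temperature_K", DEFAULT_TEMPERATURE)
                     if "temperature_K" in df.columns
                     else DEFAULT_TEMPERATURE)
        records.append(AffinityRecord(
            variant_id=str(row["variant"]), kd=kd, fit_r2=float(row["r2"]),
            temperature=temp,
            measurement_id=str(row.get("measurement_id", i)),
        ))
    return records


def estimate_panel(records, **kwargs) -> dict:
    """Group records by variant and estimate each; returns id -> estimate."""
    by_variant = {}
    for rec in records:
        by_variant.setdefault(rec.variant_id, []).append(rec)
    return {vid: estimate_binding(recs, **kwargs)
            for vid, recs in by_variant.items()}


def build_training_table(estimates: dict, score_results) -> list:
    """Join score results with binding estimates into (id, score, binder).

    Binder flag: a valid estimate (measurable dG) marks a binder; a
    below-detection estimate marks a non-binder.  Variants with
    insufficient data are left out with a warning, as are unmatched ids on
    either side.
    """
    pairs = []
    unmatched = []
    for sr in score_results:
        est = estimates.get(sr.variant_id)
        if est is None:
            unmatched.append(sr.variant_id)
            continue
        if est.below_detection:
            pairs.append((sr.variant_id, sr.score, False))
        elif est.valid:
            pairs.append((sr.variant_id, sr.score, True))
        else:
            warnings.warn(
                f"variant {sr.variant_id}: insufficient affinity data "
                f"({est.n_used} usable measurements) — left out of training",
                stacklevel=2,
            )
    score_ids = {sr.variant_id for sr in score_results}
    unmatched += [vid for vid in estimates if vid not in score_ids]
    if unmatched:
        warnings.warn(f"unmatched variant ids: {sorted(unmatched)}",
                      stacklevel=2)
    if not pairs:
        raise ValueError("no variant appears in both the score results and "
                         "the affinity estimates")
    return pairs


def write_training_table(pairs, estimates: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tscore\tmean_dG_kJ_per_mol\tbinder\n")
        for vid, score, binder in pairs:
            est = estimates.get(vid)
            dg = "" if est is None or est.mean_dG is None else f"{est.mean_dG:.2f}"
            fh.write(f"{vid}\t{score:.4f}\t{dg}\t{int(binder)}\n")
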