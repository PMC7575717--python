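"""Call 13C incorporators from control-normalized density profiles.

A family-level taxon is called an incorporator in a treatment when all of
the following hold:

1. *Detection*: its relative abundance exceeds a floor (default 1e-6, i.e.
   0.0001%) in at least three retained fractions of the amended gradient.
2. *Prevalence*: its relative abundance exceeds a floor (default 1e-3,
   i.e. 0.1%) in either the amended or the control unfractionated
   community, guarding against rare-taxon PCR noise.
3. *Pattern*: the log2(amended/control) profile across densities spans
   more than the labeling threshold (default 0.53 ~ 2·log2(1.2), the range
   implied by +/-20% labeling) and is shaped like a labeled population —
   either rising toward the heavy fractions ("well labeled") or elevated
   at both gradient ends with a dip in the middle, the bimodal "V" of a
   partially labeled population.

The pattern rules are quantitative surrogates for visual profile reading:
a Spearman correlation of log2 SA against density >= +0.6 with the maximum
in the heavy half calls well-labeled; both terminal thirds exceeding the
interior minimum by at least half the labeling threshold calls partially
labeled; a correlation <= -0.6 (abundance draining toward the light end)
or a sub-threshold range calls unlabeled; anything else is ambiguous.
All comparisons are strict, so boundary equality fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .gradient_profiles import (
    DEFAULT_EXCLUDED_FRACTIONS,
    DensityProfile,
    compute_profiles,
)
from .tables_io import AbundanceTable, FractionSample, TablesIOError

__all__ = [
    "LabelCall",
    "criterion_detection",
    "criterion_prevalence",
    "log2_range",
    "classify_pattern",
    "call_incorporators",
    "calls_to_frame",
    "score_calls",
    "DETECTION_FLOOR",
    "PREVALENCE_FLOOR",
    "LOG2_RANGE_THRESHOLD",
    "SPEARMAN_CUTOFF",
]

# Thresholds converted once from the conventional percent scale.
DETECTION_FLOOR = 1e-6  # 0.0001%
PREVALENCE_FLOOR = 1e-3  # 0.1%
LOG2_RANGE_THRESHOLD = 0.53  # ~ 2 * log2(1.2), +/-20% labeling
SPEARMAN_CUTOFF = 0.6

PATTERNS = ("well_labeled", "partially_labeled", "unlabeled", "ambiguous")


@dataclass
class LabelCall:
    """Per-(taxon, treatment) incorporation call with its evidence."""

    taxon: str
    treatment_id: str
    crit1_detect: bool
    crit2_prevalence: bool
    log2_range: float
    crit3_pattern: str
    is_incorporator: bool
    evidence: np.ndarray  # per-fraction log2 SA over retained fractions


def criterion_detection(
    ra: np.ndarray, floor: float = DETECTION_FLOOR, min_fractions: int = 3
) -> bool:
    """Detection criterion: abundance strictly above the floor in at least
    ``min_fractions`` retained fractions of the amended gradient."""
    ra = np.asarray(ra, dtype=float)
    return int((ra > floor).sum()) >= min_fractions


def criterion_prevalence(
    ra_unfrac_control: float,
    ra_unfrac_amended: float,
    floor: float = PREVALENCE_FLOOR,
) -> bool:
    """Prevalence criterion: strictly above the floor in either
    unfractionated community (control OR amended)."""
    return (ra_unfrac_control > floor) or (ra_unfrac_amended > floor)


def log2_range(log2_sa: np.ndarray, min_finite: int = 3) -> float:
    """Range (max - min) of the finite log2 SA values across fractions."""
    log2_sa = np.asarray(log2_sa, dtype=float)
    finite = log2_sa[np.isfinite(log2_sa)]
    if finite.size < min_finite:
        raise TablesIOError(
            f"need >= {min_finite} finite log2 SA values, got {finite.size}"
        )
    return float(finite.max() - finite.min())


def _heavy_half_mask(densities: np.ndarray) -> np.ndarray:
    # ties at the median count as heavy
    return densities >= np.median(densities)


def classify_pattern(
    log2_sa: np.ndarray,
    densities: np.ndarray,
    range_threshold: float = LOG2_RANGE_THRESHOLD,
    spearman_cutoff: float = SPEARMAN_CUTOFF,
    v_margin: float | None = None,
) -> str:
    """Classify a log2 SA profile as well_labeled / partially_labeled /
    unlabeled / ambiguous.  ``v_margin`` defaults to half the labeling
    threshold."""
    log2_sa = np.asarray(log2_sa, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if log2_sa.shape != densities.shape:
        raise TablesIOError("log2 SA and density vectors are misaligned")
    if v_margin is None:
        v_margin = range_threshold / 2.0
    finite = np.isfinite(log2_sa)
    if finite.sum() < 3:
        return "ambiguous"
    y = log2_sa[finite]
    d = densities[finite]
    if float(y.max() - y.min()) <= range_threshold:
        return "unlabeled"
    rho = spearmanr(d, y).statistic
    if np.isnan(rho):
        rho = 0.0
    if rho >= spearman_cutoff:
        heavy = _heavy_half_mask(d)  # maximum must lie in the heavy half
        if y[heavy].max() == y.max():
            return "well_labeled"
    # V shape: both terminal thirds rise above the interior minimum.  The
    # whole third must be elevated (min, not max) so that a single stray
    # read in a near-empty fraction cannot fake a bimodal profile.
    order = np.argsort(-d)  # heavy -> light
    y_sorted = y[order]
    n = y_sorted.size
    k = max(1, n // 3)
    heavy_third = y_sorted[:k]
    light_third = y_sorted[-k:]
    interior = y_sorted[k : n - k]
    if interior.size:
        interior_min = interior.min()
        if (
            heavy_third.min() >= interior_min + v_margin
            and light_third.min() >= interior_min + v_margin
        ):
            return "partially_labeled"
    if rho <= -spearman_cutoff:
        return "unlabeled"
    return "ambiguous"


def _unfractionated_ra(
    table: AbundanceTable,
    samples: Sequence[FractionSample],
    treatment_id: str,
) -> pd.Series:
    cands = [
        s
        for s in samples
        if s.treatment_id == treatment_id
        and not s.fractionated
        and s.sample_id in set(table.samples)
    ]
    if not cands:
        raise TablesIOError(
            f"no unfractionated sample for treatment {treatment_id!r}"
        )
    tf = [s for s in cands if s.timepoint.upper() == "TF"]
    chosen = (tf or cands)[-1]
    return table.column(chosen.sample_id)


def call_incorporators(
    table: AbundanceTable,
    samples: Sequence[FractionSample],
    treatment_id: str,
    detection_floor: float = DETECTION_FLOOR,
    prevalence_floor: float = PREVALENCE_FLOOR,
    range_threshold: float = LOG2_RANGE_THRESHOLD,
    spearman_cutoff: float = SPEARMAN_CUTOFF,
    excluded_fractions: Sequence[int] = DEFAULT_EXCLUDED_FRACTIONS,
    batch_normalize: bool = True,
) -> list[LabelCall]:
    """Apply the three criteria to every taxon of one amended treatment.

    Input tables are assumed to be aggregated to the rank at which calls
    are wanted (conventionally family); :func:`sipgrad.tables_io.aggregate_taxa`
    performs the aggregation when finer-grained tables are supplied.
    """
    profiles = compute_profiles(
        table,
        samples,
        treatment_id,
        excluded_fractions=excluded_fractions,
        batch_normalize=batch_normalize,
    )
    by_taxon = {p.taxon: p for p in profiles}
    control_tid = next(
        s.control_treatment_id
        for s in samples
        if s.treatment_id == treatment_id and s.control_treatment_id
    )
    unfrac_amended = _unfractionated_ra(table, samples, treatment_id)
    unfrac_control = _unfractionated_ra(table, samples, control_tid)

    calls: list[LabelCall] = []
    for taxon in sorted(by_taxon):
        p: DensityProfile = by_taxon[taxon]
        crit1 = criterion_detection(p.ra_amended, detection_floor)
        crit2 = criterion_prevalence(
            float(unfrac_control.get(taxon, 0.0)),
            float(unfrac_amended.get(taxon, 0.0)),
            prevalence_floor,
        )
        finite = np.isfinite(p.log2_sa)
        if finite.sum() >= 3:
            rng = log2_range(p.log2_sa)
            pattern = classify_pattern(
                p.log2_sa,
                p.densities,
                range_threshold=range_threshold,
                spearman_cutoff=spearman_cutoff,
            )
        else:
            rng = float("nan")
            pattern = "ambiguous"
        is_inc = (
            crit1
            and crit2
            and pattern in ("well_labeled", "partially_labeled")
            and np.isfinite(rng)
            and rng > range_threshold
        )
        calls.append(
            LabelCall(
                taxon=taxon,
                treatment_id=treatment_id,
                crit1_detect=crit1,
                crit2_prevalence=crit2,
                log2_range=rng,
                crit3_pattern=pattern,
                is_incorporator=bool(is_inc),
                evidence=p.log2_sa,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[LabelCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [c.taxon for c in calls],
            "treatment_id": [c.treatment_id for c in calls],
            "crit1_detect": [c.crit1_detect for c in calls],
            "crit2_prevalence": [c.crit2_prevalence for c in calls],
            "log2_range": [c.log2_range for c in calls],
            "crit3_pattern": [c.crit3_pattern for c in calls],
            "is_incorporator": [c.is_incorporator for c in calls],
        }
    )


def score_calls(
    calls: Sequence[LabelCall],
    truth: pd.DataFrame,
    positive_atom_fraction: float = 0.0,
    positive_cell_fraction: float = 0.0,
) -> dict[str, float]:
    """Score calls against a simulation truth table.

    Positives are taxa with ``label_atom_fraction > positive_atom_fraction``
    and ``labeled_cell_fraction > positive_cell_fraction``; negatives are
    taxa with ``label_atom_fraction == 0``.  Returns sensitivity, false
    positive rate and the underlying counts.
    """
    called = {c.taxon for c in calls if c.is_incorporator}
    labeled = truth.index[
        (truth["label_atom_fraction"] > positive_atom_fraction)
        & (truth["labeled_cell_fraction"] > positive_cell_fraction)
    ]
    unlabeled = truth.index[truth["label_atom_fraction"] == 0]
    tp = sum(t in called for t in labeled)
    fp = sum(t in called for t in unlabeled)
    return {
        "sensitivity": tp / len(labeled) if len(labeled) else float("nan"),
        "fpr": fp / len(unlabeled) if len(unlabeled) else float("nan"),
        "tp": float(tp),
        "fp": float(fp),
        "n_positive": float(len(labeled)),
        "n_negative": float(len(unlabeled)),
    }
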