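"""Per-taxon density profiles along the CsCl gradient.

For a taxon *i* in amended treatment *k* with a parallel unamended control,
over the retained fractions *j*:

    SA_ijk  = RA_ijk / RA_ijk[control]          (control normalization)
    fSA_ijk = SA_ijk / sum_j SA_ijk             (relative distribution, sums to 1)
    mean density_ik = sum_j fSA_ijk * d_jk      (fSA-weighted CsCl density)

The mean density is the per-taxon summary of how far its DNA sits toward
the heavy end of the gradient; heavier mean density in the amended
treatment indicates more 13C incorporation.  The heaviest and lightest
fractions are excluded before any of this, because in a real gradient they
are mixed with CsCl or overlay water.  Densities from different CsCl
batches are aligned by shifting each batch so its whole-sample reference
density coincides with the cross-batch mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    AbundanceTable,
    FractionSample,
    InsufficientFractionsError,
    PairedProfiles,
    TablesIOError,
    pair_with_control,
)

__all__ = [
    "DensityProfile",
    "exclude_end_fractions",
    "standardized_abundance",
    "relative_distribution",
    "mean_density",
    "normalize_batch_densities",
    "compute_profiles",
    "DEFAULT_EXCLUDED_FRACTIONS",
]

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_FRACTIONS = (1, 10)


@dataclass
class DensityProfile:
    """Control-normalized density profile of one taxon in one treatment."""

    taxon: str
    treatment_id: str
    fractions: list[int]
    densities: np.ndarray  # g mL^-1, batch-normalized
    ra_amended: np.ndarray
    ra_control: np.ndarray
    sa: np.ndarray
    log2_sa: np.ndarray
    fsa: np.ndarray
    mean_density: float


def exclude_end_fractions(
    fractions: Sequence[int],
    excluded: Sequence[int] = DEFAULT_EXCLUDED_FRACTIONS,
    min_remaining: int = 3,
) -> list[int]:
    """Drop the mixed terminal fractions (default 1 and 10), preserving order."""
    if len(fractions) < 5:
        raise InsufficientFractionsError(
            f"need >= 5 fractions before exclusion, got {len(fractions)}"
        )
    kept = [f for f in fractions if f not in set(excluded)]
    if len(kept) < min_remaining:
        raise InsufficientFractionsError(
            f"only {len(kept)} fraction(s) remain after excluding {tuple(excluded)}"
        )
    return kept


def standardized_abundance(
    ra_amended: np.ndarray,
    ra_control: np.ndarray,
    pseudo: float | None = None,
) -> np.ndarray:
    """Per-fraction amended/control abundance ratio (SA).

    Zero control abundances are replaced by a pseudo-abundance — half the
    smallest nonzero control abundance in the gradient unless ``pseudo``
    overrides it — so SA stays finite while preserving rank structure;
    each substitution is logged.
    """
    ra_amended = np.asarray(ra_amended, dtype=float)
    ra_control = np.asarray(ra_control, dtype=float)
    if ra_amended.shape != ra_control.shape:
        raise TablesIOError("amended and control vectors are misaligned")
    nonzero = ra_control[ra_control > 0]
    if nonzero.size == 0:
        raise TablesIOError("all-zero control vector: SA undefined")
    if pseudo is None:
        pseudo = float(nonzero.min()) / 2.0
    control = ra_control.copy()
    n_zero = int((control == 0).sum())
    if n_zero:
        logger.info(
            "substituted pseudo-abundance %.3g for %d zero control fraction(s)",
            pseudo,
            n_zero,
        )
        control[control == 0] = pseudo
    return ra_amended / control


def relative_distribution(sa: np.ndarray) -> np.ndarray:
    """Normalize SA across fractions to the relative distribution fSA."""
    sa = np.asarray(sa, dtype=float)
    total = sa.sum()
    if total <= 0:
        raise TablesIOError("sum of SA is zero: fSA undefined")
    return sa / total


def mean_density(fsa: np.ndarray, densities: np.ndarray) -> float:
    """fSA-weighted mean CsCl density of the profile (g mL^-1)."""
    fsa = np.asarray(fsa, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if fsa.shape != densities.shape:
        raise TablesIOError("fSA and density vectors are misaligned")
    return float(np.dot(fsa, densities))


def normalize_batch_densities(
    samples: Sequence[FractionSample],
) -> dict[str, float]:
    """Align fraction densities across CsCl batches.

    Each batch's reference is the measured density of its whole
    unfractionated sample(s) (their mean when several exist).  Every
    fractionated density in a batch is shifted by (cross-batch mean of
    references − that batch's reference), so references coincide after
    adjustment.  Returns ``{sample_id: adjusted density}`` for the
    fractionated samples.
    """
    refs: dict[str, list[float]] = {}
    for s in samples:
        if not s.fractionated and s.csdensity is not None:
            refs.setdefault(s.batch_id, []).append(float(s.csdensity))
    batches = {s.batch_id for s in samples if s.fractionated}
    missing = sorted(b for b in batches if b not in refs)
    if missing:
        raise TablesIOError(
            f"batch(es) lacking an unfractionated reference density: {missing}"
        )
    batch_ref = {b: float(np.mean(v)) for b, v in refs.items()}
    grand = float(np.mean([batch_ref[b] for b in sorted(batches)]))
    shifts = {b: grand - batch_ref[b] for b in batches}
    return {
        s.sample_id: float(s.csdensity) + shifts[s.batch_id]
        for s in samples
        if s.fractionated and s.csdensity is not None
    }


def compute_profiles(
    table: AbundanceTable,
    samples: Sequence[FractionSample],
    treatment_id: str,
    excluded_fractions: Sequence[int] = DEFAULT_EXCLUDED_FRACTIONS,
    batch_normalize: bool = True,
    taxa: Sequence[str] | None = None,
) -> list[DensityProfile]:
    """Full profile computation for every taxon of one amended treatment:
    pair with control, exclude end fractions, batch-normalize densities,
    then SA -> fSA -> mean density."""
    paired = pair_with_control(table, samples, treatment_id)
    kept = exclude_end_fractions(paired.fraction_indices, excluded_fractions)
    pos = [paired.fraction_indices.index(j) for j in kept]
    densities = paired.densities[pos]
    if batch_normalize:
        adjusted = normalize_batch_densities(samples)
        frac_sample = {
            int(s.fraction_index): s.sample_id  # type: ignore[arg-type]
            for s in samples
            if s.treatment_id == treatment_id and s.fractionated
        }
        densities = np.array([adjusted[frac_sample[j]] for j in kept])
    # gradient-wide pseudo-abundance from the retained control fractions
    ctrl_block = paired.ra_control.iloc[:, pos].to_numpy(float)
    nonzero = ctrl_block[ctrl_block > 0]
    pseudo = float(nonzero.min()) / 2.0 if nonzero.size else None
    profiles: list[DensityProfile] = []
    for taxon in taxa if taxa is not None else paired.ra_amended.index:
        ra_am = paired.ra_amended.loc[taxon].to_numpy(float)[pos]
        ra_ct = paired.ra_control.loc[taxon].to_numpy(float)[pos]
        if ra_ct.max() == 0 and ra_am.max() == 0:
            continue  # taxon absent from this gradient entirely
        sa = standardized_abundance(ra_am, ra_ct, pseudo=pseudo)
        with np.errstate(divide="ignore"):
            log2_sa = np.log2(sa)
        fsa = relative_distribution(sa)
        profiles.append(
            DensityProfile(
                taxon=str(taxon),
                treatment_id=treatment_id,
                fractions=list(kept),
                densities=densities,
                ra_amended=ra_am,
                ra_control=ra_ct,
                sa=sa,
                log2_sa=log2_sa,
                fsa=fsa,
                mean_density=mean_density(fsa, densities),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[DensityProfile]) -> pd.DataFrame:
    """Tidy (taxon, treatment, mean_density) table for export/heatmaps."""
    return pd.DataFrame(
        {
            "taxon": [p.taxon for p in profiles],
            "treatment_id": [p.treatment_id for p in profiles],
            "mean_density": [p.mean_density for p in profiles],
        }
    )
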