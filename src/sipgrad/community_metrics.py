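"""Unfractionated community-structure utilities.

Relative abundances of whole (unfractionated) communities are standardized
per taxon to z-scores so that dominance by one blooming family does not
swamp the rest of the community; z-score differences between an amended
treatment and its control highlight responding taxa (|delta| > 1 flags a
change above one standard deviation).  Bray-Curtis distances and
average-linkage cut-height clustering support community comparison, with
an option to exclude a dominant taxon (and renormalize) before computing
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .tables_io import AbundanceTable, MissingColumnError, TablesIOError

__all__ = [
    "ZScoreMatrix",
    "zscore_by_taxon",
    "zscore_change",
    "bray_curtis",
    "hierarchical_clusters",
]


@dataclass
class ZScoreMatrix:
    """Per-taxon standardized abundances with the centering used."""

    values: pd.DataFrame  # taxa × samples
    mean: pd.Series  # per-taxon mean relative abundance
    sd: pd.Series  # per-taxon sd (ddof per zscore_by_taxon)

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise MissingColumnError(f"unknown sample_id {sample_id!r}")
        return self.values[sample_id]


def zscore_by_taxon(table: AbundanceTable, ddof: int = 1) -> ZScoreMatrix:
    """Standardize each taxon's relative abundance across all samples.

    Uses the sample standard deviation (ddof=1) by default.  Taxa with
    zero variance get z = 0 everywhere, with a warning.
    """
    if len(table.samples) < 2:
        raise TablesIOError("z-scores need >= 2 samples")
    x = table.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa assigned z = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = sd.replace(0, np.nan)
    z = x.sub(mu, axis=0).div(safe_sd, axis=0).fillna(0.0)
    return ZScoreMatrix(values=z, mean=mu, sd=sd)


def zscore_change(
    z: ZScoreMatrix,
    amended_sample: str,
    control_sample: str,
    flag_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-taxon z-score difference between an amended sample and its
    control, flagged where |delta| exceeds ``flag_threshold``."""
    delta = z.column(amended_sample) - z.column(control_sample)
    return pd.DataFrame(
        {"delta": delta, "flagged": delta.abs() > flag_threshold}
    )


def bray_curtis(
    table: AbundanceTable, exclude_taxa: Sequence[str] = ()
) -> pd.DataFrame:
    """Sample × sample Bray-Curtis dissimilarity matrix.

    Excluded taxa (e.g. a bloom-dominant family) are dropped and the
    remaining proportions renormalized per sample before computing
    D_xy = sum|x_i - y_i| / sum(x_i + y_i).
    """
    if len(table.samples) < 2:
        raise TablesIOError("distance matrix needs >= 2 samples")
    values = table.values.drop(index=list(exclude_taxa), errors="ignore")
    if values.empty:
        raise TablesIOError("empty community after taxon exclusion")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise TablesIOError("sample with zero abundance after exclusion")
    norm = values / totals
    dist = squareform(pdist(norm.T.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(dist, index=values.columns, columns=values.columns)


def hierarchical_clusters(
    distance: pd.DataFrame,
    method: str = "average",
    cut: float = 0.70,
) -> pd.Series:
    """Cut an agglomerative tree on a distance matrix at a dissimilarity.

    Labels are renumbered deterministically in order of each cluster's
    first member (matrix column order), starting at 1.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TablesIOError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise TablesIOError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method=method)
    raw = fcluster(tree, t=cut, criterion="distance")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    index = (
        distance.index
        if isinstance(distance, pd.DataFrame)
        else pd.RangeIndex(d.shape[0])
    )
    return pd.Series(labels, index=index, name="cluster")
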