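"""Tabular data model and I/O for SIP gradient experiments.

The central objects are:

* :class:`FractionSample` — one sample: either a single CsCl gradient
  fraction (with its buoyant density) or a whole unfractionated community.
* :class:`AbundanceTable` — a taxa × samples matrix of relative abundances
  (proportions in [0, 1]; columns sum to 1), optionally carrying the read
  depths it was normalized from.
* :class:`GrowthSeries` — per-treatment time series of bacterioplankton
  abundance, cell dimensions, DOC and TDAA-C used by the growth module.

All on-disk formats are plain TSV/CSV so that every pipeline stage output
can be re-read by this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FractionSample",
    "AbundanceTable",
    "GrowthSeries",
    "PairedProfiles",
    "TablesIOError",
    "MissingColumnError",
    "NonNumericDensityError",
    "DuplicateSampleError",
    "ColumnSumError",
    "NegativeAbundanceError",
    "FractionIndexError",
    "MissingControlError",
    "InsufficientFractionsError",
    "read_metadata",
    "write_metadata",
    "read_abundance_table",
    "write_abundance_table",
    "read_growth_series",
    "pair_with_control",
    "aggregate_taxa",
]

METADATA_COLUMNS = [
    "sample_id",
    "treatment_id",
    "control_treatment_id",
    "fraction_index",
    "csdensity",
    "batch_id",
    "timepoint",
    "fractionated",
]

GROWTH_COLUMNS = [
    "treatment_id",
    "time_d",
    "BA",
    "cell_L_um",
    "cell_W_um",
    "DOC_uM",
    "TDAA_C_uM",
]

_COLUMN_SUM_TOL = 1e-9


class TablesIOError(ValueError):
    """Base class for tabular-input validation failures."""


class MissingColumnError(TablesIOError):
    """A required column or sample is absent."""


class NonNumericDensityError(TablesIOError):
    """A CsCl density could not be parsed as a positive real."""


class DuplicateSampleError(TablesIOError):
    """The same sample_id occurs more than once."""


class ColumnSumError(TablesIOError):
    """An abundance column does not sum to 1 (or to <= 1 with filtering)."""


class NegativeAbundanceError(TablesIOError):
    """Negative relative abundance or count encountered."""


class FractionIndexError(TablesIOError):
    """Fraction index outside the valid 1..10 range or inconsistent with
    the fractionated flag."""


class MissingControlError(TablesIOError):
    """An amended treatment has no resolvable control gradient."""


class InsufficientFractionsError(TablesIOError):
    """Too few shared fractions remain to pair amended and control."""


@dataclass(frozen=True)
class FractionSample:
    """One gradient fraction or one unfractionated community sample.

    ``csdensity`` is mandatory for fractionated samples (the measured CsCl
    density of that fraction, g mL^-1).  For unfractionated samples it is
    optional and, when present, is interpreted as the whole-sample density
    of that CsCl batch, which serves as the reference for cross-batch
    density normalization.
    """

    sample_id: str
    treatment_id: str
    control_treatment_id: str = ""
    fraction_index: int | None = None
    csdensity: float | None = None
    batch_id: str = ""
    timepoint: str = ""
    fractionated: bool = False

    def __post_init__(self) -> None:
        if self.fractionated:
            if self.fraction_index is None:
                raise FractionIndexError(
                    f"{self.sample_id}: fractionated sample lacks fraction_index"
                )
            if not 1 <= int(self.fraction_index) <= 10:
                raise FractionIndexError(
                    f"{self.sample_id}: fraction_index {self.fraction_index} "
                    "outside 1..10"
                )
            if self.csdensity is None or not np.isfinite(self.csdensity):
                raise NonNumericDensityError(
                    f"{self.sample_id}: fractionated sample lacks a numeric "
                    "csdensity"
                )
            if self.csdensity <= 0:
                raise NonNumericDensityError(
                    f"{self.sample_id}: csdensity must be positive, got "
                    f"{self.csdensity}"
                )
        else:
            if self.fraction_index is not None:
                raise FractionIndexError(
                    f"{self.sample_id}: unfractionated sample carries a "
                    "fraction_index"
                )


@dataclass
class AbundanceTable:
    """Taxa × samples relative-abundance matrix.

    ``values`` is a DataFrame with taxon labels as the index and sample ids
    as columns; entries are proportions in [0, 1].  ``counts_total`` records
    per-sample read depth when the table was normalized from counts.
    ``column_deficit`` records, per sample, how far below 1 a column sums
    (nonzero only when rows were filtered upstream).
    """

    values: pd.DataFrame
    counts_total: pd.Series | None = None
    column_deficit: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise DuplicateSampleError(f"duplicated sample_id(s): {list(dups)}")
        if (self.values.values < 0).any():
            raise NegativeAbundanceError("negative relative abundance")
        sums = self.values.sum(axis=0)
        if (sums > 1 + _COLUMN_SUM_TOL).any():
            bad = sums[sums > 1 + _COLUMN_SUM_TOL]
            raise ColumnSumError(
                f"columns sum above 1: {dict(bad.round(6))}"
            )
        if self.column_deficit is None:
            self.column_deficit = (1.0 - sums).clip(lower=0.0)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise MissingColumnError(f"unknown sample_id {sample_id!r}")
        return self.values[sample_id]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "AbundanceTable":
        """Normalize an integer count matrix column-wise to proportions."""
        if (counts.values < 0).any():
            raise NegativeAbundanceError("negative counts")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise ColumnSumError(f"zero-read sample(s): {empty}")
        return cls(values=counts / totals, counts_total=totals.astype(int))


@dataclass
class GrowthSeries:
    """Time series of growth and chemistry measurements for one treatment.

    Any measured series may be missing (NaN) at individual timepoints;
    downstream operations skip missing values per series rather than
    imputing them.
    """

    treatment_id: str
    times: np.ndarray  # days
    BA: np.ndarray  # cells L^-1
    cell_L: np.ndarray  # um, major axis
    cell_W: np.ndarray  # um, minor axis
    DOC: np.ndarray  # umol C L^-1
    TDAA_C: np.ndarray  # umol C L^-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise TablesIOError(
                f"{self.treatment_id}: times must be strictly increasing"
            )
        for name in ("BA", "cell_L", "cell_W", "DOC", "TDAA_C"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise TablesIOError(
                    f"{self.treatment_id}: {name} length mismatch"
                )
            setattr(self, name, arr)
        present = self.BA[np.isfinite(self.BA)]
        if (present <= 0).any():
            raise TablesIOError(
                f"{self.treatment_id}: BA must be positive where present"
            )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    # round_trip parsing so write -> read is the identity on float values
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_metadata(path: str | Path) -> list[FractionSample]:
    """Read a sample metadata table (TSV/CSV with the required headers)."""
    df = _read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"metadata lacks column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"]
        raise DuplicateSampleError(f"duplicated sample_id(s): {list(dups)}")
    samples: list[FractionSample] = []
    for _, row in df.iterrows():
        fractionated = _parse_bool(row["fractionated"])
        frac = row["fraction_index"]
        frac_idx = None if pd.isna(frac) else int(frac)
        dens = row["csdensity"]
        if pd.isna(dens):
            density = None
        else:
            try:
                density = float(dens)
            except (TypeError, ValueError) as exc:
                raise NonNumericDensityError(
                    f"{row['sample_id']}: csdensity {dens!r} is not numeric"
                ) from exc
        ctrl = row["control_treatment_id"]
        samples.append(
            FractionSample(
                sample_id=str(row["sample_id"]),
                treatment_id=str(row["treatment_id"]),
                control_treatment_id="" if pd.isna(ctrl) else str(ctrl),
                fraction_index=frac_idx,
                csdensity=density,
                batch_id=str(row["batch_id"]),
                timepoint=str(row["timepoint"]),
                fractionated=fractionated,
            )
        )
    return samples


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes"}:
        return True
    if text in {"false", "f", "0", "no"}:
        return False
    raise TablesIOError(f"cannot parse boolean flag {value!r}")


def write_metadata(samples: Sequence[FractionSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "treatment_id": s.treatment_id,
                "control_treatment_id": s.control_treatment_id,
                "fraction_index": "" if s.fraction_index is None else s.fraction_index,
                "csdensity": "" if s.csdensity is None else repr(s.csdensity),
                "batch_id": s.batch_id,
                "timepoint": s.timepoint,
                "fractionated": s.fractionated,
            }
        )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep=sep, index=False)


def read_abundance_table(
    path: str | Path, metadata_path: str | Path
) -> tuple[AbundanceTable, list[FractionSample]]:
    """Read and cross-validate an abundance table with its sample metadata.

    The first column of the abundance file holds taxon labels; remaining
    columns are samples.  If column sums exceed 1 the matrix is interpreted
    as raw read counts and renormalized to proportions (the read depths are
    kept on ``counts_total``).  Every sample column must appear in the
    metadata, and every fractionated sample must carry a positive density.
    """
    samples = read_metadata(metadata_path)
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise MissingColumnError("abundance table needs a taxon column and >=1 sample")
    matrix = raw.set_index(raw.columns[0])
    matrix.index.name = "taxon"
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise TablesIOError(f"non-numeric abundance value: {exc}") from exc
    known = {s.sample_id for s in samples}
    unknown = [c for c in matrix.columns if c not in known]
    if unknown:
        raise MissingColumnError(
            f"abundance sample(s) absent from metadata: {unknown}"
        )
    sums = matrix.sum(axis=0)
    if (sums > 1 + 1e-6).any():
        table = AbundanceTable.from_counts(matrix)
    else:
        table = AbundanceTable(values=matrix)
    used = [s for s in samples if s.sample_id in set(matrix.columns)]
    return table, used


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    out = table.values.copy()
    out.index.name = "taxon"
    # repr-precision floats so a read round-trips bit-exactly
    out.to_csv(path, sep=sep, float_format="%.17g")


def read_growth_series(path: str | Path) -> dict[str, GrowthSeries]:
    """Read growth/chemistry time series, one :class:`GrowthSeries` per
    treatment_id found in the file."""
    df = _read_table(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"growth table lacks column(s): {missing}")
    out: dict[str, GrowthSeries] = {}
    for tid, grp in df.groupby("treatment_id", sort=True):
        grp = grp.sort_values("time_d")
        out[str(tid)] = GrowthSeries(
            treatment_id=str(tid),
            times=grp["time_d"].to_numpy(float),
            BA=grp["BA"].to_numpy(float),
            cell_L=grp["cell_L_um"].to_numpy(float),
            cell_W=grp["cell_W_um"].to_numpy(float),
            DOC=grp["DOC_uM"].to_numpy(float),
            TDAA_C=grp["TDAA_C_uM"].to_numpy(float),
        )
    return out


@dataclass
class PairedProfiles:
    """Aligned amended/control per-fraction abundances for one treatment.

    Pairing is by fraction index, not by density: fraction j of the amended
    gradient is compared with fraction j of its parallel control gradient.
    ``densities`` are those of the amended gradient's fractions (the control
    gradient may differ slightly; any batch offset is handled by the batch
    density normalization step).
    """

    treatment_id: str
    control_treatment_id: str
    fraction_indices: list[int]  # ascending: fraction 1 is heaviest
    densities: np.ndarray  # amended-gradient densities, g mL^-1
    ra_amended: pd.DataFrame  # taxa × fractions
    ra_control: pd.DataFrame  # taxa × fractions, same shape

    def taxon(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.ra_amended.loc[name].to_numpy(float),
            self.ra_control.loc[name].to_numpy(float),
        )


def pair_with_control(
    table: AbundanceTable,
    samples: Sequence[FractionSample],
    treatment_id: str,
    min_shared: int = 3,
) -> PairedProfiles:
    """Align the fractionated samples of an amended treatment with its
    parallel unamended-control gradient, fraction index by fraction index."""
    amended = [
        s
        for s in samples
        if s.treatment_id == treatment_id
        and s.fractionated
        and s.sample_id in set(table.samples)
    ]
    if not amended:
        raise MissingControlError(
            f"no fractionated samples for treatment {treatment_id!r}"
        )
    ctrl_ids = {s.control_treatment_id for s in amended if s.control_treatment_id}
    if len(ctrl_ids) != 1:
        raise MissingControlError(
            f"treatment {treatment_id!r} lacks a unique control_treatment_id "
            f"(found {sorted(ctrl_ids)})"
        )
    control_tid = ctrl_ids.pop()
    control = [
        s
        for s in samples
        if s.treatment_id == control_tid
        and s.fractionated
        and s.sample_id in set(table.samples)
    ]
    if not control:
        raise MissingControlError(
            f"control treatment {control_tid!r} has no fractionated samples"
        )
    am_by_frac = {int(s.fraction_index) for s in amended}  # type: ignore[arg-type]
    ct_by_frac = {int(s.fraction_index) for s in control}  # type: ignore[arg-type]
    shared = sorted(am_by_frac & ct_by_frac)
    if len(shared) < min_shared:
        raise InsufficientFractionsError(
            f"only {len(shared)} shared fraction(s) between {treatment_id!r} "
            f"and {control_tid!r}; need >= {min_shared}"
        )
    am_map = {int(s.fraction_index): s for s in amended}  # type: ignore[arg-type]
    ct_map = {int(s.fraction_index): s for s in control}  # type: ignore[arg-type]
    densities = np.array([am_map[j].csdensity for j in shared], dtype=float)
    ra_amended = table.values[[am_map[j].sample_id for j in shared]].copy()
    ra_amended.columns = shared
    ra_control = table.values[[ct_map[j].sample_id for j in shared]].copy()
    ra_control.columns = shared
    return PairedProfiles(
        treatment_id=treatment_id,
        control_treatment_id=control_tid,
        fraction_indices=shared,
        densities=densities,
        ra_amended=ra_amended,
        ra_control=ra_control,
    )


def aggregate_taxa(
    table: AbundanceTable, mapping: Mapping[str, str]
) -> AbundanceTable:
    """Sum rows sharing a target label (e.g. ASV/genus -> family).

    Taxa absent from ``mapping`` keep their own label.
    """
    labels = [mapping.get(t, t) for t in table.taxa]
    grouped = table.values.groupby(labels, sort=True).sum()
    grouped.index.name = "taxon"
    return AbundanceTable(
        values=grouped,
        counts_total=table.counts_total,
        column_deficit=table.column_deficit,
    )
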