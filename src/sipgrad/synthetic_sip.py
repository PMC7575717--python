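"""Forward simulator for paired amended/control DNA-SIP experiments.

The simulator emulates the physical chain from community composition to
per-fraction amplicon counts:

1. Each taxon's unlabeled DNA bands at a GC-dependent buoyant density
   (linear Schildkraut-type calibration, default 1.660 + 0.00098·GC%).
2. In the amended (isotope-labeled) treatment, a configurable fraction of
   each taxon's population carries newly synthesized DNA whose density is
   shifted upward in proportion to its 13C atom fraction (default full
   shift 0.036 g mL^-1).  The taxon's DNA mass is thus a two-component
   Gaussian mixture over density (within-taxon smear sd ``smear_sd``).
3. The gradient is fractionated into equal-width density bins ordered
   heavy-to-light (fraction 1 collected first from the tube bottom is the
   heaviest).  Mass falling outside the simulated span is assigned to the
   terminal fractions, mimicking the mixed end fractions that the analysis
   later excludes.
4. Per-fraction reads are drawn multinomially with probabilities
   proportional to per-taxon DNA mass in that bin; unfractionated samples
   are multinomial draws from the growth-weighted community proportions.

The control treatment is generated identically with the atom fraction set
to zero everywhere and growth taken from each taxon's control growth
factor, so GC-driven density structure is shared between treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tables_io import AbundanceTable, FractionSample

__all__ = [
    "TaxonSpec",
    "GradientSpec",
    "SimulationResult",
    "demo_community",
    "demo_gradient",
    "unlabeled_density",
    "labeled_density_shift",
    "incorporation_percent",
    "fraction_bins",
    "expected_fraction_profiles",
    "simulate_experiment",
    "GC_DENSITY_INTERCEPT",
    "GC_DENSITY_SLOPE",
    "FULL_LABEL_SHIFT",
]

# Linear GC -> buoyant density calibration (g mL^-1); package defaults,
# overridable per call.
GC_DENSITY_INTERCEPT = 1.660
GC_DENSITY_SLOPE = 0.00098
# Density shift of fully 13C-labeled DNA (g mL^-1).  A measured shift of
# 0.010 g mL^-1 under this calibration corresponds to ~28% incorporation.
FULL_LABEL_SHIFT = 0.036


@dataclass(frozen=True)
class TaxonSpec:
    """Ground-truth parameters of one simulated family-level taxon.

    ``growth_factor`` is the fold-change of the taxon over the incubation in
    the amended treatment; ``control_growth_factor`` (default 1.0) plays the
    same role in the unamended control, letting e.g. bottle-effect bloomers
    grow equally in both treatments.  ``labeled_cell_fraction`` is the share
    of the final population whose DNA carries the label, so values < 1
    produce the bimodal, partially labeled profiles.
    """

    name: str
    gc_percent: float
    baseline_ra: float
    growth_factor: float = 1.0
    label_atom_fraction: float = 0.0
    labeled_cell_fraction: float = 0.0
    control_growth_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_percent <= 100:
            raise ValueError(f"{self.name}: gc_percent outside [0, 100]")
        if not 0 <= self.baseline_ra <= 1:
            raise ValueError(f"{self.name}: baseline_ra outside [0, 1]")
        if not 0 <= self.label_atom_fraction <= 1:
            raise ValueError(f"{self.name}: label_atom_fraction outside [0, 1]")
        if not 0 <= self.labeled_cell_fraction <= 1:
            raise ValueError(f"{self.name}: labeled_cell_fraction outside [0, 1]")
        if self.growth_factor < 0 or self.control_growth_factor < 0:
            raise ValueError(f"{self.name}: growth factors must be >= 0")


@dataclass(frozen=True)
class GradientSpec:
    """Geometry and sampling parameters of one simulated CsCl gradient."""

    n_fractions: int = 10
    fraction_volume: float = 325.0  # uL
    density_center: float = 1.73  # g mL^-1
    density_span: float = 0.10  # g mL^-1 covered by the fractions
    smear_sd: float = 0.008  # g mL^-1 within-taxon spread
    depth: int = 100_000  # reads per fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 5:
            raise ValueError("n_fractions must be >= 5")
        if self.density_span <= 0:
            raise ValueError("density_span must be positive")
        if self.smear_sd <= 0:
            raise ValueError("smear_sd must be positive")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")


@dataclass
class SimulationResult:
    """Bundle returned by :func:`simulate_experiment`."""

    table: AbundanceTable
    samples: list[FractionSample]
    truth: pd.DataFrame  # per-taxon ground truth for scoring
    amended_id: str
    control_id: str


def unlabeled_density(
    gc_percent: float | np.ndarray,
    intercept: float = GC_DENSITY_INTERCEPT,
    slope: float = GC_DENSITY_SLOPE,
) -> float | np.ndarray:
    """Buoyant density (g mL^-1) of unlabeled DNA from its GC content."""
    gc = np.asarray(gc_percent, dtype=float)
    if np.any(gc < 0) or np.any(gc > 100):
        raise ValueError("gc_percent outside [0, 100]")
    out = intercept + slope * gc
    return float(out) if np.isscalar(gc_percent) else out


def labeled_density_shift(
    label_atom_fraction: float | np.ndarray,
    full_shift: float = FULL_LABEL_SHIFT,
) -> float | np.ndarray:
    """Density increase (g mL^-1) of DNA at a given 13C atom fraction."""
    a = np.asarray(label_atom_fraction, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("label_atom_fraction outside [0, 1]")
    out = full_shift * a
    return float(out) if np.isscalar(label_atom_fraction) else out


def incorporation_percent(
    density_shift: float, full_shift: float = FULL_LABEL_SHIFT
) -> float:
    """Invert the labeling calibration: percent 13C incorporation implied
    by an observed buoyant-density shift."""
    if full_shift <= 0:
        raise ValueError("full_shift must be positive")
    return 100.0 * density_shift / full_shift


def demo_community() -> list[TaxonSpec]:
    """A 20-taxon marine bacterioplankton community for simulation studies.

    The roster mixes fast-responding copiotrophs that incorporate the
    labeled substrate (atom fractions 0.3-1.0, labeled cell fractions
    0.6-1.0), an abundant slow-growing oligotroph that becomes only
    partially labeled (a SAR11-like bimodal case), weakly labeled edge
    cases, and twelve unlabeled taxa — including a bloom-former that grows
    equally in amended and control incubations (the classic false-positive
    trap) and low-GC oligotrophs whose unlabeled DNA bands light.  GC
    contents span 29-65%, the realistic range for marine prokaryotes.
    """
    return [
        # 13C incorporators
        TaxonSpec("Rhodobacteraceae", 58, 0.040, 6.0, 1.00, 1.0),
        TaxonSpec("Vibrionaceae", 46, 0.020, 8.0, 1.00, 0.7),
        TaxonSpec("Erythrobacteraceae", 63, 0.020, 4.0, 0.60, 1.0),
        TaxonSpec("Hyphomonadaceae", 59, 0.015, 3.0, 0.50, 0.6),
        TaxonSpec("SAR86_clade", 42, 0.050, 2.0, 0.35, 0.8),
        TaxonSpec("Pseudoalteromonadaceae", 40, 0.020, 5.0, 0.30, 0.9),
        # labeled but weak / partial edge cases
        TaxonSpec("SAR11_II", 30, 0.200, 1.3, 0.50, 0.25),
        TaxonSpec("OM1_clade", 52, 0.030, 1.5, 0.20, 0.4),
        # unlabeled community
        TaxonSpec("Alteromonadaceae", 44, 0.080, 12.0, 0.0, 0.0, 12.0),
        TaxonSpec("Flavobacteriaceae", 34, 0.060, 2.0, 0.0, 0.0, 1.5),
        TaxonSpec("Oceanospirillaceae", 48, 0.040, 1.2),
        TaxonSpec("Rhodospirillaceae", 65, 0.050, 1.0),
        TaxonSpec("SAR11_Ia", 29, 0.150, 0.8, 0.0, 0.0, 0.8),
        TaxonSpec("SAR202_clade", 54, 0.040, 0.9),
        TaxonSpec("Nitrospinaceae", 47, 0.020, 1.0),
        TaxonSpec("Salinisphaeraceae", 64, 0.015, 1.1),
        TaxonSpec("Anaerolineaceae", 53, 0.020, 1.0),
        TaxonSpec("Marine_Group_I", 33, 0.080, 0.7, 0.0, 0.0, 0.7),
        TaxonSpec("Sva0996_marine_group", 50, 0.020, 1.0),
        TaxonSpec("Puniceicoccaceae", 52, 0.030, 1.0),
    ]


def demo_gradient(seed: int = 0, depth: int = 100_000) -> GradientSpec:
    """Gradient geometry matched to :func:`demo_community`.

    Ten fractions spanning 1.685-1.755 g mL^-1 so that, as in a real
    fractionation, the retained fractions 2-9 all contain appreciable DNA:
    unlabeled DNA of the community's GC range (29-65%) bands at
    1.688-1.724 and smears to ~1.745, and fully labeled DNA reaches
    ~1.753.  A wider span would leave the heaviest retained fractions
    essentially DNA-free, making their relative abundances pure
    compositional noise — the situation the end-fraction exclusion exists
    to avoid.
    """
    return GradientSpec(
        density_center=1.72,
        density_span=0.07,
        smear_sd=0.008,
        depth=depth,
        seed=seed,
    )


def fraction_bins(gradient: GradientSpec) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width density bins over the gradient span.

    Returns ``(edges, centers)`` with fractions ordered heavy -> light
    (fraction 1 heaviest): ``edges`` is length ``n_fractions + 1`` and
    strictly decreasing, ``centers[j]`` is the density assigned to
    fraction ``j + 1``.
    """
    lo = gradient.density_center - gradient.density_span / 2
    hi = gradient.density_center + gradient.density_span / 2
    edges = np.linspace(hi, lo, gradient.n_fractions + 1)
    if edges[0] - edges[1] <= 0:
        raise ValueError("degenerate gradient: zero-width bins")
    centers = (edges[:-1] + edges[1:]) / 2
    return edges, centers


def _taxon_bin_mass(
    taxon: TaxonSpec,
    gradient: GradientSpec,
    edges: np.ndarray,
    labeled: bool,
    gc_intercept: float,
    gc_slope: float,
    full_shift: float,
) -> np.ndarray:
    """Fraction of the taxon's DNA mass landing in each fraction bin.

    Terminal bins are extended to +/- infinity so all edge mass ends up in
    fractions 1 and n.
    """
    mu_unlabeled = unlabeled_density(taxon.gc_percent, gc_intercept, gc_slope)
    weights = [(1.0, mu_unlabeled)]
    if labeled and taxon.labeled_cell_fraction > 0:
        shift = labeled_density_shift(taxon.label_atom_fraction, full_shift)
        weights = [
            (1.0 - taxon.labeled_cell_fraction, mu_unlabeled),
            (taxon.labeled_cell_fraction, mu_unlabeled + shift),
        ]
    open_edges = edges.copy()
    open_edges[0] = np.inf
    open_edges[-1] = -np.inf
    mass = np.zeros(len(edges) - 1)
    for w, mu in weights:
        if w <= 0:
            continue
        upper = norm.cdf(open_edges[:-1], loc=mu, scale=gradient.smear_sd)
        lower = norm.cdf(open_edges[1:], loc=mu, scale=gradient.smear_sd)
        mass += w * (upper - lower)
    return mass


def expected_fraction_profiles(
    taxa: Sequence[TaxonSpec],
    gradient: GradientSpec,
    labeled: bool = True,
    gc_intercept: float = GC_DENSITY_INTERCEPT,
    gc_slope: float = GC_DENSITY_SLOPE,
    full_shift: float = FULL_LABEL_SHIFT,
) -> pd.DataFrame:
    """Analytic expected per-fraction read proportions (taxa × fractions).

    Each column gives the expected multinomial probabilities of
    :func:`simulate_experiment` in that fraction; this is the independent
    analytic reference the sampled tables converge to as depth grows.
    """
    taxa = sorted(taxa, key=lambda t: t.name)
    edges, _ = fraction_bins(gradient)
    growth = np.array(
        [
            t.growth_factor if labeled else t.control_growth_factor
            for t in taxa
        ]
    )
    base = np.array([t.baseline_ra for t in taxa])
    final = base * growth
    final = final / final.sum()
    mass = np.vstack(
        [
            _taxon_bin_mass(
                t, gradient, edges, labeled, gc_intercept, gc_slope, full_shift
            )
            for t in taxa
        ]
    )
    joint = final[:, None] * mass
    totals = joint.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = joint / totals
    # a fraction with no DNA at all amplifies background uniformly
    empty = (totals == 0).ravel()
    if empty.any():
        probs[:, empty] = 1.0 / len(taxa)
    return pd.DataFrame(
        probs,
        index=[t.name for t in taxa],
        columns=[f"F{j + 1}" for j in range(gradient.n_fractions)],
    )


def simulate_experiment(
    taxa: Sequence[TaxonSpec],
    gradient: GradientSpec,
    amended_id: str = "13C",
    control_id: str = "control",
    batch_id: str = "B1",
    gc_intercept: float = GC_DENSITY_INTERCEPT,
    gc_slope: float = GC_DENSITY_SLOPE,
    full_shift: float = FULL_LABEL_SHIFT,
) -> SimulationResult:
    """Simulate one paired amended/control SIP experiment.

    Produces fractionated samples for both treatments plus unfractionated
    TF community samples, as one :class:`AbundanceTable` with metadata.
    Taxa are processed in sorted-name order, which makes the draw (and so
    the output) invariant to the order the caller lists them in.
    """
    taxa = sorted(taxa, key=lambda t: t.name)
    names = [t.name for t in taxa]
    total_base = sum(t.baseline_ra for t in taxa)
    if not np.isclose(total_base, 1.0, atol=1e-6):
        raise ValueError(f"baseline_ra must sum to 1 (got {total_base})")
    edges, centers = fraction_bins(gradient)
    rng = np.random.default_rng(gradient.seed)

    columns: dict[str, np.ndarray] = {}
    samples: list[FractionSample] = []
    for tid, labeled, ctrl_ref in (
        (amended_id, True, control_id),
        (control_id, False, ""),
    ):
        probs = expected_fraction_profiles(
            taxa, gradient, labeled, gc_intercept, gc_slope, full_shift
        ).to_numpy()
        for j in range(gradient.n_fractions):
            sid = f"{tid}_F{j + 1}"
            counts = rng.multinomial(gradient.depth, probs[:, j])
            columns[sid] = counts
            samples.append(
                FractionSample(
                    sample_id=sid,
                    treatment_id=tid,
                    control_treatment_id=ctrl_ref,
                    fraction_index=j + 1,
                    csdensity=float(centers[j]),
                    batch_id=batch_id,
                    timepoint="TF",
                    fractionated=True,
                )
            )
        growth = np.array(
            [t.growth_factor if labeled else t.control_growth_factor for t in taxa]
        )
        community = np.array([t.baseline_ra for t in taxa]) * growth
        community = community / community.sum()
        sid = f"{tid}_unfrac"
        columns[sid] = rng.multinomial(gradient.depth, community)
        samples.append(
            FractionSample(
                sample_id=sid,
                treatment_id=tid,
                control_treatment_id=ctrl_ref,
                fraction_index=None,
                csdensity=gradient.density_center,
                batch_id=batch_id,
                timepoint="TF",
                fractionated=False,
            )
        )

    counts = pd.DataFrame(columns, index=pd.Index(names, name="taxon"))
    table = AbundanceTable.from_counts(counts)
    truth = pd.DataFrame(
        {
            "taxon": names,
            "gc_percent": [t.gc_percent for t in taxa],
            "baseline_ra": [t.baseline_ra for t in taxa],
            "growth_factor": [t.growth_factor for t in taxa],
            "control_growth_factor": [t.control_growth_factor for t in taxa],
            "label_atom_fraction": [t.label_atom_fraction for t in taxa],
            "labeled_cell_fraction": [t.labeled_cell_fraction for t in taxa],
        }
    ).set_index("taxon")
    return SimulationResult(
        table=table,
        samples=samples,
        truth=truth,
        amended_id=amended_id,
        control_id=control_id,
    )
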