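"""Synthetic data: ground-truth profiles, sorted samples, bulk mixtures.

The generator plants, for each reference cell type, a disjoint set of marker
peaks that are highly accessible in that type and nearly closed elsewhere;
background peaks share log-normal accessibility across all types; "module
decoy" peaks are open in every cell type (mimicking universally accessible
chromatin, to be vetoed by the module filter).  The uncharacterized component
has background-level accessibility but is exactly closed at every planted
marker — the idealization under which the deficit 1 - sum(p) identifies its
fraction.  Counts are negative-binomial (gamma-Poisson) with a single
dispersion phi around mean = profile x study batch multiplier x depth/1e6,
with multiplicative log-normal batch effects per (study, peak block).  All
peaks share one length so the TPM-like transform recovers the profile scale
exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import CountsMatrix, ReferenceProfile
from .intervals import GenomicRegion, PeakSet
from .markers import ChromatinModules

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference_truth",
    "simulate_sorted_samples",
    "simulate_bulk",
    "simulate_pseudobulk_from_cells",
    "truth_reference_profile",
    "truth_modules",
]

UNCHARACTERIZED = "uncharacterized"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a small sorted-cell collection: 5 cell types observed in
    3 studies with 4 samples each, plus a screening panel of 10 external
    tissue groups (4 samples each, one batch study per tissue) standing in for
    the diverse-organ samples that marker selection tests against; 100 planted
    markers per type, 1000 shared background peaks and 50 universally open
    decoys; sequencing depth 1e6 fragments per sample, negative-binomial
    dispersion 0.2, study batch multipliers log-normal with sigma 0.2,
    Dirichlet concentration 1 for bulk mixtures and an uncharacterized
    fraction drawn uniformly from [0, 0.6].
    """

    n_cell_types: int = 5
    markers_per_type: int = 100
    n_background_peaks: int = 1000
    n_module_decoys: int = 50
    n_studies: int = 3
    samples_per_study: int = 4
    n_tissue_groups: int = 10
    tissue_samples: int = 4
    depth: float = 1e6
    phi: float = 0.2
    marker_high: float = 300.0
    marker_low: float = 0.5
    background_mean: float = 30.0
    background_sigma: float = 1.0
    decoy_mean: float = 300.0
    batch_sigma: float = 0.2
    batch_block: int = 50
    alpha: float = 1.0
    include_uncharacterized: bool = True
    uncharacterized_range: tuple[float, float] = (0.0, 0.6)
    leaky_markers: float = 0.0  # nonzero: uncharacterized marker accessibility (robustness)
    peak_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.markers_per_type, self.n_background_peaks,
               self.n_studies, self.samples_per_study, self.peak_length) < 1:
            raise ValueError("counts and sizes must be positive")
        if self.n_module_decoys < 0 or self.n_tissue_groups < 0:
            raise ValueError("n_module_decoys and n_tissue_groups must be >= 0")
        if self.depth <= 0 or self.phi < 0 or self.alpha <= 0:
            raise ValueError("depth and alpha must be > 0 and phi >= 0")
        lo, hi = self.uncharacterized_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("uncharacterized_range must lie within [0, 1]")

    def cell_type_names(self) -> list[str]:
        return [f"celltype_{i + 1}" for i in range(self.n_cell_types)]

    def tissue_group_names(self) -> list[str]:
        return [f"tissue_{i + 1}" for i in range(self.n_tissue_groups)]


@dataclass
class GroundTruth:
    """The generator's hidden state: mean profiles and marker annotation.

    ``profiles`` is peaks x (cell types + uncharacterized), TPM-like scale
    (each column sums to 1e6); ``marker_ids`` maps each cell type to its
    planted marker peak ids; ``decoy_ids`` are the universally open decoys;
    ``batch_multipliers`` maps study -> per-peak multiplier vector.
    """

    peaks: PeakSet
    cell_types: list[str]
    profiles: pd.DataFrame
    marker_ids: dict[str, list[str]]
    decoy_ids: list[str]
    batch_multipliers: dict[str, np.ndarray]
    tissue_profiles: pd.DataFrame | None = None  # peaks x external-tissue groups
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def marker_flags(self) -> dict[str, np.ndarray]:
        ids = list(self.peaks.ids)
        index = {pid: i for i, pid in enumerate(ids)}
        out = {}
        for ct, mids in self.marker_ids.items():
            flags = np.zeros(len(ids), dtype=bool)
            for m in mids:
                flags[index[m]] = True
            out[ct] = flags
        return out


def _make_peaks(n: int, length: int) -> PeakSet:
    # synthetic genome: peaks tiled across 4 autosome-like chromosomes
    chroms = [f"chr{c}" for c in range(1, 5)]
    regions = []
    per = -(-n // len(chroms))
    k = 0
    for chrom in chroms:
        for j in range(per):
            if k >= n:
                break
            start = j * (2 * length)
            regions.append(GenomicRegion(chrom, start, start + length))
            k += 1
    return PeakSet(regions, "hg38")


def simulate_reference_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the ground-truth mean accessibility profiles.

    Markers are high in their own type and near-closed elsewhere; background
    peaks share one log-normal mean across all types; decoys are open in every
    type.  The uncharacterized column equals the background at background
    peaks, the decoy mean at decoys, and exactly 0 (or ``leaky_markers``) at
    planted markers.  External-tissue groups (the ENCODE-organ role of the
    marker screen) share the background and decoy accessibility but are closed
    at every planted marker.  Columns are rescaled to sum to 1e6, so profiles
    live on the TPM-like scale.
    """
    rng = np.random.default_rng(config.seed)
    cts = config.cell_type_names()
    n_markers = config.n_cell_types * config.markers_per_type
    n_total = n_markers + config.n_background_peaks + config.n_module_decoys
    peaks = _make_peaks(n_total, config.peak_length)
    if len(peaks) != n_total:
        raise RuntimeError("peak construction lost regions")

    # assign roles over the sorted peak set, shuffled so roles are interleaved
    order = rng.permutation(n_total)
    marker_rows = {
        ct: np.sort(order[i * config.markers_per_type:(i + 1) * config.markers_per_type])
        for i, ct in enumerate(cts)
    }
    bg_rows = np.sort(order[n_markers:n_markers + config.n_background_peaks])
    decoy_rows = np.sort(order[n_markers + config.n_background_peaks:])

    profiles = np.zeros((n_total, config.n_cell_types + 1))
    bg = config.background_mean * rng.lognormal(
        -config.background_sigma**2 / 2, config.background_sigma, size=bg_rows.size
    )
    profiles[bg_rows, :] = bg[:, None]
    profiles[decoy_rows, :] = config.decoy_mean
    for i, ct in enumerate(cts):
        rows = marker_rows[ct]
        profiles[rows, :config.n_cell_types] = config.marker_low
        profiles[rows, i] = config.marker_high * rng.uniform(0.5, 1.5, size=rows.size)
        profiles[rows, -1] = config.leaky_markers
    # external tissues: background + decoys open, every planted marker closed
    tissues = config.tissue_group_names()
    tissue_prof = np.zeros((n_total, len(tissues)))
    if tissues:
        tissue_prof[bg_rows, :] = bg[:, None]  # ubiquitous chromatin: same everywhere
        tissue_prof[decoy_rows, :] = config.decoy_mean
        tissue_prof = tissue_prof / tissue_prof.sum(axis=0, keepdims=True) * 1e6

    # TPM-like scale: each column sums to 1e6
    profiles = profiles / profiles.sum(axis=0, keepdims=True) * 1e6

    ids = list(peaks.ids)
    marker_ids = {ct: [ids[r] for r in marker_rows[ct]] for ct in cts}
    decoy_ids = [ids[r] for r in decoy_rows]

    # per-(study, block) multiplicative batch effects, shared by all samples of
    # a study; each external tissue group is its own study of origin
    multipliers: dict[str, np.ndarray] = {}
    n_blocks = -(-n_total // config.batch_block)
    studies = [f"study_{s + 1}" for s in range(config.n_studies)]
    studies += [f"encode_{t}" for t in tissues]
    for study in studies:
        block_mult = rng.lognormal(0.0, config.batch_sigma, size=n_blocks)
        multipliers[study] = np.repeat(block_mult, config.batch_block)[:n_total]

    return GroundTruth(
        peaks, cts,
        pd.DataFrame(profiles, index=ids, columns=cts + [UNCHARACTERIZED]),
        marker_ids, decoy_ids, multipliers,
        pd.DataFrame(tissue_prof, index=ids, columns=tissues) if tissues else None,
        config,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; Poisson in the phi -> 0 limit."""
    mean = np.clip(mean, 0.0, None)
    if phi < 1e-12:
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam).astype(float)


def simulate_sorted_samples(
    truth: GroundTruth, config: SimulationConfig | None = None, seed: int | None = None
) -> CountsMatrix:
    """Sorted-cell count matrix with cell-type and study labels.

    counts_jk ~ NB(mean = profile_j(cell type of k) x study multiplier_j x
    depth/1e6, dispersion phi).  External-tissue groups, when configured,
    contribute ``tissue_samples`` samples each under the study label
    ``"encode"`` and are labelled by their group name.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    profiles = truth.profiles[truth.cell_types].to_numpy()
    n_peaks = profiles.shape[0]
    sample_ids: list[str] = []
    meta_rows = []
    cols = []
    for i, ct in enumerate(truth.cell_types):
        for s in range(config.n_studies):
            study = f"study_{s + 1}"
            mult = truth.batch_multipliers[study]
            for r in range(config.samples_per_study):
                mean = profiles[:, i] * mult * (config.depth / 1e6)
                cols.append(_nb_draw(rng, mean, config.phi))
                sid = f"{ct}_{study}_s{r + 1}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cell_type": ct, "study": study})
    if truth.tissue_profiles is not None:
        tissue_prof = truth.tissue_profiles.to_numpy()
        for t, tissue in enumerate(truth.tissue_profiles.columns):
            study = f"encode_{tissue}"
            mult = truth.batch_multipliers[study]
            for r in range(config.tissue_samples):
                mean = tissue_prof[:, t] * mult * (config.depth / 1e6)
                cols.append(_nb_draw(rng, mean, config.phi))
                sid = f"{tissue}_{study}_s{r + 1}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cell_type": tissue, "study": study})
    values = np.column_stack(cols)
    assert values.shape == (n_peaks, len(sample_ids))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountsMatrix(values, truth.peaks, sample_ids, meta)


def simulate_bulk(
    truth: GroundTruth,
    n_samples: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    noise: bool = True,
    uncharacterized_fractions: np.ndarray | None = None,
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Bulk mixtures with known proportions.

    Cell-type proportions are Dirichlet(alpha); when uncharacterized cells are
    included their fraction is drawn uniformly from the configured range (or
    fixed via ``uncharacterized_fractions``) and the Dirichlet draw is scaled
    to the remainder.  Expected bulk profile = profiles @ p; counts are NB
    around expectation x depth/1e6, or exactly the expectation with
    ``noise=False``.  Returns the counts and the exact proportion table.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    cts = truth.cell_types
    profiles = truth.profiles.to_numpy()  # peaks x (types + unchar)
    p_ct = rng.dirichlet(np.full(len(cts), config.alpha), size=n_samples)
    if config.include_uncharacterized:
        if uncharacterized_fractions is not None:
            p_u = np.asarray(uncharacterized_fractions, float)
            if p_u.shape != (n_samples,):
                raise ValueError("uncharacterized_fractions must have length n_samples")
        else:
            lo, hi = config.uncharacterized_range
            p_u = rng.uniform(lo, hi, size=n_samples)
    else:
        p_u = np.zeros(n_samples)
    p_full = np.column_stack([p_ct * (1.0 - p_u)[:, None], p_u])
    expected = profiles @ p_full.T  # peaks x samples, TPM-like scale
    mean = expected * (config.depth / 1e6)
    if noise:
        values = _nb_draw(rng, mean, config.phi)
    else:
        values = mean
    sample_ids = [f"bulk_{k + 1}" for k in range(n_samples)]
    proportions = pd.DataFrame(p_full, index=sample_ids, columns=cts + [UNCHARACTERIZED])
    return CountsMatrix(values, truth.peaks, sample_ids), proportions


def simulate_pseudobulk_from_cells(
    cell_profiles: np.ndarray,
    cell_labels: list[str] | np.ndarray,
    peaks: PeakSet,
    sample_id: str = "pseudobulk_1",
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Pseudobulk = per-peak mean over member cells; truth = cell-count shares.

    ``cell_profiles`` is peaks x cells of normalized per-cell signal.
    """
    cell_labels = np.asarray(cell_labels)
    if cell_labels.size == 0:
        raise ValueError("need at least one cell")
    if cell_profiles.shape[1] != cell_labels.size:
        raise ValueError("one label per cell required")
    values = cell_profiles.mean(axis=1, keepdims=True)
    cts = sorted(set(cell_labels.tolist()))
    shares = [(cell_labels == ct).mean() for ct in cts]
    proportions = pd.DataFrame([shares], index=[sample_id], columns=cts)
    return CountsMatrix(values, peaks, [sample_id]), proportions


# ---------------------------------------------------------------------------
# Bridges to the rest of the pipeline
# ---------------------------------------------------------------------------

def truth_reference_profile(truth: GroundTruth) -> ReferenceProfile:
    """The generator's exact reference: R = true profiles, v = 0, markers = planted."""
    R = truth.profiles[truth.cell_types].to_numpy()
    return ReferenceProfile(
        truth.peaks, list(truth.cell_types), R, np.zeros_like(R),
        truth.marker_flags(), truth.peaks.genome_build,
    )


def truth_modules(truth: GroundTruth) -> ChromatinModules:
    """Module decoys packaged as a universal chromatin-module set."""
    regions = [GenomicRegion.from_id(pid) for pid in truth.decoy_ids]
    modules = {"module_universal_1": PeakSet(regions, truth.peaks.genome_build)}
    return ChromatinModules(modules, {"module_universal_1": "universal"},
                            {"module_universal_1"})


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
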