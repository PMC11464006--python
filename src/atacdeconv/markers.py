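"""Cell-type-specific marker peak selection.

From pairwise differential-accessibility results, a peak becomes a candidate
marker of a cell type when its accessibility is higher (log2FC above a
threshold) in that type than in every other group — other reference types and
external-tissue groups alike.  Candidates are ranked by the maximum
BH-adjusted p-value over all those contrasts, truncated to the top N, and must
recur in at least ``min_folds`` of ``n_folds`` leave-one-fold-out repetitions.
Two filters follow: removal of markers overlapping universal or non-exempt
tissue chromatin modules, and a correlation-based selection that retains the
markers co-varying most strongly in tumor bulk samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountsMatrix, NormalizedMatrix
from .differential import DAResult, pairwise_da
from .intervals import GenomicRegion, PeakSet

__all__ = [
    "MarkerSelectionParams",
    "ChromatinModules",
    "MarkerSet",
    "select_fold_markers",
    "stability_filter",
    "make_folds",
    "module_filter",
    "correlation_prune",
    "find_correlated",
    "run_marker_discovery",
    "read_modules_tsv",
    "default_exemptions",
]


@dataclass
class MarkerSelectionParams:
    """Tunable thresholds of the marker-selection pipeline.

    Defaults: log2FC > 0.2 in every contrast, top 200 candidates per fold,
    ten folds with recurrence in at least three, correlation cutoff at the
    90th percentile of pairwise Pearson values.
    """

    lfc_min: float = 0.2
    top_n: int = 200
    n_folds: int = 10
    min_folds: int = 3
    corr_percentile: float = 90.0
    lfc_mode: str = "all"  # "all": above threshold in every contrast; "any": in at least one
    prune_mode: str = "keep_correlated"  # or "drop_correlated"

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (1 <= self.min_folds <= self.n_folds):
            raise ValueError("min_folds must lie in [1, n_folds]")
        if not (0 < self.corr_percentile < 100):
            raise ValueError("corr_percentile must lie in (0, 100)")
        if self.lfc_mode not in ("all", "any"):
            raise ValueError("lfc_mode must be 'all' or 'any'")
        if self.prune_mode not in ("keep_correlated", "drop_correlated"):
            raise ValueError("prune_mode must be 'keep_correlated' or 'drop_correlated'")


@dataclass
class ChromatinModules:
    """Published open-chromatin modules used to veto non-specific markers.

    ``modules`` maps module id -> regions; ``classes`` labels each module
    (e.g. immune, endothelial, stromal, other-tissue); ``universal_ids`` are
    the modules accessible across essentially all tissues.
    """

    modules: dict[str, PeakSet]
    classes: dict[str, str]
    universal_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for mid in self.universal_ids:
            if mid not in self.modules:
                raise ValueError(f"universal module {mid!r} not defined")
        for mid in self.modules:
            if mid not in self.classes:
                raise ValueError(f"module {mid!r} has no class label")


@dataclass
class MarkerSet:
    """Ordered marker peak ids per cell type, with per-marker provenance.

    ``provenance`` has columns cell_type, peak_id, fold_count, module_ok,
    corr_ok (the two flags record filter survival).
    """

    markers: dict[str, list[str]]
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ct, ids in self.markers.items():
            for pid in ids:
                if pid in seen and seen[pid] != ct:
                    raise ValueError(
                        f"marker {pid} assigned to both {seen[pid]!r} and {ct!r}"
                    )
                seen[pid] = ct

    def to_frame(self) -> pd.DataFrame:
        return self.provenance.copy()


def default_exemptions(cell_types: list[str]) -> dict[str, set[str]]:
    """Default module-class exemptions per cell type.

    Endothelial cell types keep endothelial modules, fibroblasts keep stromal
    modules, and every other reference type (immune by assumption) keeps
    immune modules.
    """
    out: dict[str, set[str]] = {}
    for ct in cell_types:
        low = ct.lower()
        if "endothelial" in low:
            out[ct] = {"endothelial"}
        elif "fibro" in low:
            out[ct] = {"stromal"}
        else:
            out[ct] = {"immune"}
    return out


# ---------------------------------------------------------------------------
# Candidate selection & stability
# ---------------------------------------------------------------------------

def select_fold_markers(
    da: list[DAResult],
    target_cell_type: str,
    params: MarkerSelectionParams,
    groups: list[str] | None = None,
) -> list[str]:
    """Top candidate markers of one cell type from one fold's DA results.

    Candidates must show log2FC above ``lfc_min`` favoring the target in all
    (or any, per ``lfc_mode``) of its contrasts; they are ranked ascending by
    the maximum BH-adjusted p across those contrasts, ties broken by larger
    minimum log2FC then peak id, and truncated to ``top_n``.
    """
    oriented: list[DAResult] = []
    for r in da:
        if r.group_a == target_cell_type:
            oriented.append(r)
        elif r.group_b == target_cell_type:
            oriented.append(r.reversed())
    if groups is not None:
        expected = {g for g in groups if g != target_cell_type}
        covered = {r.group_b for r in oriented}
        missing = expected - covered
        if missing:
            raise ValueError(
                f"missing contrast(s) for {target_cell_type!r}: {sorted(missing)}"
            )
    if not oriented:
        raise ValueError(f"no contrasts involve cell type {target_cell_type!r}")
    peak_ids = oriented[0].peak_ids
    lfc = np.vstack([r.lfc for r in oriented])
    padj = np.vstack([r.padj for r in oriented])
    above = lfc > params.lfc_min
    qualifies = above.all(axis=0) if params.lfc_mode == "all" else above.any(axis=0)
    max_padj = padj.max(axis=0)
    min_lfc = lfc.min(axis=0)
    cand = np.nonzero(qualifies)[0]
    ranked = sorted(cand, key=lambda j: (max_padj[j], -min_lfc[j], peak_ids[j]))
    return [peak_ids[j] for j in ranked[: params.top_n]]


def stability_filter(
    per_fold_markers: list[list[str]], params: MarkerSelectionParams
) -> list[tuple[str, int]]:
    """Keep ids recurring in at least ``min_folds`` folds, with their counts.

    Output is ordered by decreasing fold count, then id.
    """
    if len(per_fold_markers) != params.n_folds:
        raise ValueError(
            f"expected {params.n_folds} fold lists, got {len(per_fold_markers)}"
        )
    counts: dict[str, int] = {}
    for fold in per_fold_markers:
        for pid in set(fold):
            counts[pid] = counts.get(pid, 0) + 1
    kept = [(pid, c) for pid, c in counts.items() if c >= params.min_folds]
    kept.sort(key=lambda x: (-x[1], x[0]))
    return kept


def make_folds(
    sample_ids: list[str],
    labels: list[str] | np.ndarray,
    n_folds: int,
    seed: int,
) -> list[list[str]]:
    """Stratified leave-out partitions: fold f holds the samples EXCLUDED from
    analysis run f (analysis set = complement of partition f).

    Stratification is by cell type: each type's samples are shuffled and dealt
    round-robin across folds, so every analysis set retains samples of every
    type.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    if labels.size != len(sample_ids):
        raise ValueError("one label per sample required")
    if n_folds < 2:
        raise ValueError("need at least two folds")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for ct in sorted(set(labels.tolist())):
        ids = [s for s, l in zip(sample_ids, labels) if l == ct]
        if len(ids) < 2:
            raise ValueError(
                f"cell type {ct!r} has {len(ids)} sample(s); some analysis set would lose it"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for k, s in enumerate(ids):
            folds[k % n_folds].append(s)
    return folds


# ---------------------------------------------------------------------------
# Module filtering
# ---------------------------------------------------------------------------

def read_modules_tsv(path: str | Path, genome_build: str = "hg38") -> ChromatinModules:
    """Read a modules TSV (module_id, chrom, start, end, class); rows of class
    'universal' form the universal module set."""
    df = pd.read_csv(path, sep="\t")
    required = {"module_id", "chrom", "start", "end", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"modules file missing column(s): {sorted(missing)}")
    modules: dict[str, list[GenomicRegion]] = {}
    classes: dict[str, str] = {}
    for mid, chrom, start, end, cls in df[
        ["module_id", "chrom", "start", "end", "class"]
    ].itertuples(index=False, name=None):
        mid = str(mid)
        modules.setdefault(mid, []).append(GenomicRegion(str(chrom), int(start), int(end)))
        classes[mid] = str(cls)
    universal = {mid for mid, cl in classes.items() if cl == "universal"}
    return ChromatinModules(
        {mid: PeakSet(regs, genome_build) for mid, regs in modules.items()},
        classes,
        universal,
    )


def _overlaps_any(region: GenomicRegion, peaks: PeakSet) -> bool:
    arrays = peaks._chrom_arrays().get(region.chrom)
    if arrays is None:
        return False
    starts, ends, _ = arrays
    return bool(((starts < region.end) & (ends > region.start)).any())


def module_filter(
    markers: MarkerSet,
    modules: ChromatinModules,
    exemptions: dict[str, set[str]] | None = None,
) -> MarkerSet:
    """Remove markers overlapping universal modules or non-exempt tissue modules.

    A marker of cell type c is removed iff it overlaps (>= 1 bp) any universal
    module, or any module whose class is not in c's exempt set.  When
    ``exemptions`` is None the default mapping applies (immune types keep
    immune modules, endothelial keep endothelial, fibroblasts keep stromal).
    """
    if exemptions is None:
        exemptions = default_exemptions(list(markers.markers))
    else:
        for ct, classes in exemptions.items():
            unknown = classes - set(modules.classes.values())
            if unknown:
                raise ValueError(
                    f"exemption for {ct!r} names unknown class(es): {sorted(unknown)}"
                )
    new_markers: dict[str, list[str]] = {}
    prov = markers.provenance.set_index(["cell_type", "peak_id"])
    prov["module_ok"] = True
    for ct, ids in markers.markers.items():
        exempt = exemptions.get(ct, set())
        kept: list[str] = []
        for pid in ids:
            region = GenomicRegion.from_id(pid)
            removed = False
            for mid, mod_peaks in modules.modules.items():
                veto = mid in modules.universal_ids or modules.classes[mid] not in exempt
                if veto and _overlaps_any(region, mod_peaks):
                    removed = True
                    break
            if removed:
                prov.loc[(ct, pid), "module_ok"] = False
            else:
                kept.append(pid)
        new_markers[ct] = kept
    return MarkerSet(new_markers, prov.reset_index())


# ---------------------------------------------------------------------------
# Correlation pruning (findCorrelation-style scan)
# ---------------------------------------------------------------------------

def find_correlated(corr: np.ndarray, cutoff: float) -> list[int]:
    """Indices flagged by the pairwise correlation scan.

    Pairs (i, j), i < j, are visited in column-major order; for each pair with
    |r| > cutoff whose members are both unflagged, the member with the larger
    mean absolute off-diagonal correlation is flagged (ties flag the lower
    index).
    """
    corr = np.asarray(corr, float)
    n = corr.shape[0]
    if n < 2:
        return []
    abs_corr = np.abs(corr)
    mean_abs = (abs_corr.sum(axis=1) - np.diag(abs_corr)) / (n - 1)
    flagged: list[int] = []
    flagged_set: set[int] = set()
    for j in range(n):
        for i in range(j):
            if i in flagged_set or j in flagged_set:
                continue
            if abs_corr[i, j] > cutoff:
                victim = i if mean_abs[i] >= mean_abs[j] else j
                flagged.append(victim)
                flagged_set.add(victim)
    return flagged


def correlation_prune(
    markers: MarkerSet,
    bulk: NormalizedMatrix | CountsMatrix,
    params: MarkerSelectionParams,
) -> MarkerSet:
    """Select, per cell type, the markers co-varying most strongly in bulk data.

    The cutoff is the ``corr_percentile``-th percentile of that cell type's
    upper-triangle pairwise Pearson correlations across bulk samples.  In the
    default ``keep_correlated`` mode the flagged (most inter-correlated)
    markers are RETAINED — cell-type-specific markers are expected to co-vary
    in tumor bulk — while ``drop_correlated`` applies the conventional
    redundancy-pruning reading.  If no pair exceeds the cutoff the original
    set is kept with a warning.  Markers absent from the bulk matrix pass
    through unchanged.
    """
    if bulk.values.shape[1] < 3:
        raise ValueError("correlation pruning needs at least three bulk samples")
    row_index = {pid: i for i, pid in enumerate(bulk.peaks.ids)}
    prov = markers.provenance.set_index(["cell_type", "peak_id"])
    prov["corr_ok"] = True
    new_markers: dict[str, list[str]] = {}
    for ct, ids in markers.markers.items():
        present = [pid for pid in ids if pid in row_index]
        absent = [pid for pid in ids if pid not in row_index]
        if len(present) < 2:
            new_markers[ct] = list(ids)
            continue
        X = bulk.values[[row_index[p] for p in present], :]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        iu = np.triu_indices(len(present), k=1)
        cutoff = float(np.percentile(np.abs(corr[iu]), params.corr_percentile))
        flagged = find_correlated(corr, cutoff)
        if params.prune_mode == "keep_correlated":
            retained_idx = set(flagged)
        else:
            retained_idx = set(range(len(present))) - set(flagged)
        if not retained_idx:
            warnings.warn(
                f"correlation pruning would empty the marker set of {ct!r}; keeping it unpruned",
                stacklevel=2,
            )
            new_markers[ct] = list(ids)
            continue
        kept = [pid for k, pid in enumerate(present) if k in retained_idx]
        for pid in present:
            if pid not in kept:
                prov.loc[(ct, pid), "corr_ok"] = False
        new_markers[ct] = kept + absent
    return MarkerSet(new_markers, prov.reset_index())


# ---------------------------------------------------------------------------
# End-to-end discovery
# ---------------------------------------------------------------------------

def run_marker_discovery(
    counts: CountsMatrix,
    params: MarkerSelectionParams | None = None,
    reference_cell_types: list[str] | None = None,
    modules: ChromatinModules | None = None,
    bulk_for_prune: NormalizedMatrix | CountsMatrix | None = None,
    exemptions: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> MarkerSet:
    """Full marker pipeline: folds -> pairwise DA -> select -> stability ->
    module filter -> correlation prune.

    ``counts.sample_meta`` must carry a ``cell_type`` column; labels not in
    ``reference_cell_types`` (default: all labels) act as external-tissue
    groups — they join every contrast but are never marker targets.  The
    module filter runs only when ``modules`` is given; correlation pruning
    only when ``bulk_for_prune`` is given.
    """
    if params is None:
        params = MarkerSelectionParams()
    if counts.sample_meta is None or "cell_type" not in counts.sample_meta.columns:
        raise ValueError("counts.sample_meta must provide a 'cell_type' column")
    labels = counts.sample_meta.loc[counts.sample_ids, "cell_type"].to_numpy()
    groups = sorted(set(labels.tolist()))
    targets = reference_cell_types if reference_cell_types is not None else groups
    unknown = set(targets) - set(groups)
    if unknown:
        raise ValueError(f"reference cell type(s) absent from labels: {sorted(unknown)}")

    folds = make_folds(list(counts.sample_ids), labels, params.n_folds, seed)
    per_fold: dict[str, list[list[str]]] = {ct: [] for ct in targets}
    for held_out in folds:
        analysis_ids = [s for s in counts.sample_ids if s not in set(held_out)]
        sub = counts.subset_samples(analysis_ids)
        sub_labels = sub.sample_meta.loc[sub.sample_ids, "cell_type"].to_numpy()
        da = pairwise_da(sub, sub_labels)
        for ct in targets:
            per_fold[ct].append(select_fold_markers(da, ct, params, groups=groups))

    markers: dict[str, list[str]] = {}
    rows = []
    for ct in targets:
        kept = stability_filter(per_fold[ct], params)
        markers[ct] = [pid for pid, _ in kept]
        for pid, c in kept:
            rows.append({"cell_type": ct, "peak_id": pid, "fold_count": c,
                         "module_ok": True, "corr_ok": True})
    prov = pd.DataFrame(rows, columns=["cell_type", "peak_id", "fold_count", "module_ok", "corr_ok"])
    result = MarkerSet(markers, prov)
    if modules is not None:
        result = module_filter(result, modules, exemptions)
    if bulk_for_prune is not None:
        result = correlation_prune(result, bulk_for_prune, params)
    return result
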