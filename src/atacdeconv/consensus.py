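"""Reproducible consensus peak sets from per-sample peak calls.

Two-level iterative overlap merging: within each study the highest-scoring
peak wins among overlapping calls and must be detected in at least half of
the study's samples (both samples when a study has exactly two); at the
cell-type level only peaks detected in every study of origin survive; the
global set pools cell types, collapses once more and drops chromosome Y.
Peaks are always selected, never merged or averaged.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .intervals import GenomicRegion, PeakSet, overlap_bp, parse_bed, pool_peaks

__all__ = [
    "collapse_iterative",
    "study_reproducible",
    "celltype_consensus",
    "build_global_consensus",
    "read_manifest",
    "consensus_from_manifest",
]


def collapse_iterative(peaks: PeakSet) -> PeakSet:
    """Iterative overlap collapse: repeatedly keep the highest-scoring peak and
    remove everything overlapping it (>= 1 bp) until no peaks remain.

    Equivalent single pass: visit peaks in descending score (ties by
    (chrom, start, end)) and keep each one that overlaps nothing already kept.
    The output is overlap-free, sorted, and a subset of the input.
    """
    for r in peaks:
        if r.score is None:
            raise ValueError(f"region {r.id} has no score; collapse needs scores")
    order = sorted(peaks, key=lambda r: (-r.score, r.chrom, r.start, r.end))
    kept_by_chrom: dict[str, list[GenomicRegion]] = {}
    kept: list[GenomicRegion] = []
    for r in order:
        if any(overlap_bp(r, k) > 0 for k in kept_by_chrom.get(r.chrom, ())):
            continue
        kept.append(r)
        kept_by_chrom.setdefault(r.chrom, []).append(r)
    return PeakSet(kept, peaks.genome_build)


def _detected_in(peak: GenomicRegion, sample: PeakSet) -> bool:
    arrays = sample._chrom_arrays().get(peak.chrom)
    if arrays is None:
        return False
    starts, ends, _ = arrays
    return bool(((starts < peak.end) & (ends > peak.start)).any())


def study_reproducible(per_sample_peaks: list[PeakSet]) -> PeakSet:
    """Study-level reproducible peaks.

    Pools all samples' calls, collapses iteratively, then keeps a collapsed
    peak iff it overlaps (>= 1 bp) an original call in at least half of the
    samples (ceil(n/2); both samples when n == 2).
    """
    if not per_sample_peaks:
        raise ValueError("need at least one sample")
    n = len(per_sample_peaks)
    threshold = 2 if n == 2 else math.ceil(n / 2)
    collapsed = collapse_iterative(pool_peaks(per_sample_peaks))
    kept = [
        r
        for r in collapsed
        if sum(_detected_in(r, s) for s in per_sample_peaks) >= threshold
    ]
    return PeakSet(kept, collapsed.genome_build)


def celltype_consensus(per_study_peaks: list[PeakSet]) -> PeakSet:
    """Cell-type consensus: collapse pooled study-level peaks and keep only
    those detected (>= 1 bp overlap) in every study of origin."""
    if not per_study_peaks:
        raise ValueError("need at least one study")
    collapsed = collapse_iterative(pool_peaks(per_study_peaks))
    kept = [r for r in collapsed if all(_detected_in(r, s) for s in per_study_peaks)]
    return PeakSet(kept, collapsed.genome_build)


def build_global_consensus(per_celltype_peaks: list[PeakSet]) -> PeakSet:
    """Global consensus across cell types: one more iterative collapse of the
    pooled cell-type sets, with chromosome Y excluded."""
    collapsed = collapse_iterative(pool_peaks(per_celltype_peaks))
    kept = [r for r in collapsed if r.chrom != "chrY"]
    return PeakSet(kept, collapsed.genome_build)


# ---------------------------------------------------------------------------
# Manifest-driven pipeline
# ---------------------------------------------------------------------------

REQUIRED_MANIFEST_COLUMNS = ("path", "sample_id", "cell_type", "study")


def read_manifest(path: str | Path, min_tss_score: float | None = 5.0) -> pd.DataFrame:
    """Read a sample manifest TSV (path, sample_id, cell_type, study).

    An optional ``tss_score`` column supports the standard quality filter:
    samples below ``min_tss_score`` are dropped (pass None to disable).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {', '.join(missing)}")
    if "tss_score" in df.columns and min_tss_score is not None:
        df = df[df["tss_score"] >= min_tss_score].reset_index(drop=True)
    return df


def consensus_from_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path | None = None,
    genome_build: str = "hg38",
) -> tuple[PeakSet, dict]:
    """Run the full consensus pipeline from a manifest of per-sample BED files.

    Returns the global consensus PeakSet and a per-stage report (peak counts
    per study, cell type and overall).
    """
    base = Path(base_dir) if base_dir is not None else None
    report: dict = {"studies": {}, "cell_types": {}}
    per_celltype: list[PeakSet] = []
    for cell_type, ct_rows in manifest.groupby("cell_type", sort=True):
        per_study: list[PeakSet] = []
        for study, st_rows in ct_rows.groupby("study", sort=True):
            samples = []
            for p in st_rows["path"]:
                fp = str(base / p) if base is not None else str(p)
                samples.append(parse_bed(fp, genome_build))
            study_peaks = study_reproducible(samples)
            per_study.append(study_peaks)
            report["studies"][f"{cell_type}/{study}"] = {
                "n_samples": len(samples),
                "pooled_in": sum(len(s) for s in samples),
                "reproducible_out": len(study_peaks),
            }
        ct_peaks = celltype_consensus(per_study)
        per_celltype.append(ct_peaks)
        report["cell_types"][str(cell_type)] = len(ct_peaks)
    consensus = build_global_consensus(per_celltype)
    report["global_consensus"] = len(consensus)
    return consensus, report
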