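"""Count matrices, TPM-like normalization and reference-profile construction.

The TPM-like transform divides fragment counts by peak length and rescales each
sample so its values sum to 1e6.  Reference profiles store, per cell type, the
median (R) and interquartile range (v) of the TPM-like values across the sorted
samples of that type; the IQR later drives feature weights in the mixture fit.
Quantiles use linear interpolation between order statistics (NumPy's default,
R's type 7) — stated explicitly because the IQR feeds the fit weights.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicRegion, PeakSet

__all__ = [
    "CountsMatrix",
    "NormalizedMatrix",
    "ReferenceProfile",
    "tpm_like",
    "aggregate_matched_counts",
    "build_profile",
    "write_profile",
    "read_profile",
    "read_counts_tsv",
    "write_counts_tsv",
]

PROFILE_FORMAT_VERSION = "1"


def _check_axes(values: np.ndarray, peaks: PeakSet, sample_ids: Sequence[str]) -> None:
    if values.ndim != 2:
        raise ValueError("values must be a 2-D peaks x samples array")
    if values.shape[0] != len(peaks):
        raise ValueError(
            f"row count {values.shape[0]} does not match number of peaks {len(peaks)}"
        )
    if values.shape[1] != len(sample_ids):
        raise ValueError(
            f"column count {values.shape[1]} does not match number of samples {len(sample_ids)}"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample ids must be unique")


@dataclass
class CountsMatrix:
    """Non-negative fragment counts, peaks x samples, with optional sample metadata."""

    values: np.ndarray
    peaks: PeakSet
    sample_ids: list[str]
    sample_meta: pd.DataFrame | None = None  # indexed by sample id; cell_type, study

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_axes(self.values, self.peaks, self.sample_ids)
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta is not None:
            missing = set(self.sample_ids) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"sample_meta missing rows for: {sorted(missing)}")

    @property
    def peak_lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.peaks], dtype=float)

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(sample_ids)]
        return CountsMatrix(self.values[:, idx], self.peaks, list(sample_ids), meta)


@dataclass
class NormalizedMatrix:
    """TPM-like values on the same axes as a CountsMatrix; columns sum to 1e6."""

    values: np.ndarray
    peaks: PeakSet
    sample_ids: list[str]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_axes(self.values, self.peaks, self.sample_ids)
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("normalized columns must each sum to 1e6")


@dataclass
class ReferenceProfile:
    """Per-cell-type reference accessibility over a fixed peak set.

    R[j, i] is the median TPM-like accessibility of peak j in cell type i and
    v[j, i] its interquartile range; ``markers`` flags, per cell type, the
    peaks used as deconvolution features.
    """

    peaks: PeakSet
    cell_types: list[str]
    R: np.ndarray
    v: np.ndarray
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    genome_build: str = "hg38"

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (len(self.peaks), len(self.cell_types))
        if self.R.shape != shape or self.v.shape != shape:
            raise ValueError(f"R and v must have shape {shape}")
        if (self.R < 0).any() or (self.v < 0).any():
            raise ValueError("R and v must be non-negative")
        for ct, flags in self.markers.items():
            if ct not in self.cell_types:
                raise ValueError(f"marker flags for unknown cell type {ct!r}")
            if np.asarray(flags).shape != (len(self.peaks),):
                raise ValueError(f"marker flags for {ct!r} have wrong length")

    def marker_ids(self, cell_type: str) -> list[str]:
        flags = np.asarray(self.markers[cell_type], dtype=bool)
        return [r.id for r, f in zip(self.peaks, flags) if f]

    def all_marker_indices(self) -> np.ndarray:
        """Indices of the union of all cell types' marker peaks, in peak order."""
        any_marker = np.zeros(len(self.peaks), dtype=bool)
        for flags in self.markers.values():
            any_marker |= np.asarray(flags, dtype=bool)
        return np.nonzero(any_marker)[0]


# ---------------------------------------------------------------------------
# Normalization & aggregation
# ---------------------------------------------------------------------------

def tpm_like(counts: CountsMatrix) -> NormalizedMatrix:
    """TPM-like transform: counts / peak length, each sample rescaled to sum 1e6."""
    lengths = counts.peak_lengths
    if (lengths <= 0).any():
        raise ValueError("all peak lengths must be positive")
    rate = counts.values / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        bad = ", ".join(counts.sample_ids[i] for i in zero)
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    values = rate / totals[None, :] * 1e6
    return NormalizedMatrix(values, counts.peaks, list(counts.sample_ids), counts.sample_meta)


def aggregate_matched_counts(
    bulk: CountsMatrix,
    mapping: Mapping[int, int | None],
    ref_peaks: PeakSet,
) -> CountsMatrix:
    """Sum bulk counts onto matched reference peaks.

    Output rows are the reference peaks that received at least one bulk peak;
    multiple bulk peaks matched to one reference peak have their counts summed.
    Unmatched bulk peaks are discarded; peak lengths come from the reference.
    """
    sums: dict[int, np.ndarray] = {}
    for bi, ri in mapping.items():
        if ri is None:
            continue
        if ri in sums:
            sums[ri] = sums[ri] + bulk.values[bi]
        else:
            sums[ri] = bulk.values[bi].copy()
    if not sums:
        raise ValueError("no shared features between bulk and reference peaks")
    ref_idx = sorted(sums)
    values = np.vstack([sums[i] for i in ref_idx])
    return CountsMatrix(values, ref_peaks.subset(ref_idx), list(bulk.sample_ids), bulk.sample_meta)


def build_profile(
    norm: NormalizedMatrix,
    cell_type_labels: Mapping[str, str] | pd.Series,
) -> ReferenceProfile:
    """Per-cell-type median (R) and IQR (v) of TPM-like values.

    ``cell_type_labels`` maps sample id -> cell type; every sample of the
    matrix must be labelled.  Marker flags are left unset (filled later by
    marker selection).
    """
    labels = pd.Series(cell_type_labels)
    unknown = [s for s in norm.sample_ids if s not in labels.index]
    if unknown:
        raise ValueError(f"no cell-type label for sample(s): {unknown}")
    labels = labels.loc[norm.sample_ids]
    cell_types = sorted(labels.unique())
    n_peaks = len(norm.peaks)
    R = np.zeros((n_peaks, len(cell_types)))
    v = np.zeros((n_peaks, len(cell_types)))
    for i, ct in enumerate(cell_types):
        cols = np.nonzero((labels == ct).to_numpy())[0]
        sub = norm.values[:, cols]
        R[:, i] = np.median(sub, axis=1)
        if cols.size > 1:
            q1, q3 = np.percentile(sub, [25, 75], axis=1)
            v[:, i] = q3 - q1
    build = norm.peaks.genome_build
    return ReferenceProfile(norm.peaks, cell_types, R, v, {}, build)


# ---------------------------------------------------------------------------
# Profile & counts I/O
# ---------------------------------------------------------------------------

def write_profile(profile: ReferenceProfile, path: str | Path) -> None:
    """Write a reference profile as gzip TSV with a 3-line header."""
    cts = profile.cell_types
    with gzip.open(path, "wt") as fh:
        fh.write(f"#profile_format\t{PROFILE_FORMAT_VERSION}\n")
        fh.write(f"#genome_build\t{profile.genome_build}\n")
        fh.write(f"#cell_types\t{','.join(cts)}\n")
        cols = (
            ["peak_id", "length"]
            + [f"R:{ct}" for ct in cts]
            + [f"v:{ct}" for ct in cts]
            + [f"marker:{ct}" for ct in cts]
        )
        fh.write("\t".join(cols) + "\n")
        markers = {
            ct: np.asarray(profile.markers.get(ct, np.zeros(len(profile.peaks), bool)), dtype=bool)
            for ct in cts
        }
        for j, r in enumerate(profile.peaks):
            row = [r.id, str(r.length)]
            row += [f"{profile.R[j, i]:.10g}" for i in range(len(cts))]
            row += [f"{profile.v[j, i]:.10g}" for i in range(len(cts))]
            row += ["1" if markers[ct][j] else "0" for ct in cts]
            fh.write("\t".join(row) + "\n")


def read_profile(path: str | Path) -> ReferenceProfile:
    """Read a reference profile written by :func:`write_profile`."""
    with gzip.open(path, "rt") as fh:
        l1 = fh.readline().rstrip("\n").split("\t")
        if len(l1) != 2 or l1[0] != "#profile_format":
            raise ValueError("not a profile file (missing format header)")
        if l1[1] != PROFILE_FORMAT_VERSION:
            raise ValueError(f"unsupported profile format version {l1[1]!r}")
        build = fh.readline().rstrip("\n").split("\t")[1]
        cts = fh.readline().rstrip("\n").split("\t")[1].split(",")
        df = pd.read_csv(fh, sep="\t")
    for ct in cts:
        for block in ("R", "v", "marker"):
            if f"{block}:{ct}" not in df.columns:
                raise ValueError(f"profile file missing column {block}:{ct}")
    regions = [GenomicRegion.from_id(pid) for pid in df["peak_id"]]
    peaks = PeakSet(regions, build)
    order = {r.id: k for k, r in enumerate(peaks)}
    perm = np.array([order[pid] for pid in df["peak_id"]])
    inv = np.argsort(perm)
    R = df[[f"R:{ct}" for ct in cts]].to_numpy(float)[inv]
    v = df[[f"v:{ct}" for ct in cts]].to_numpy(float)[inv]
    markers = {
        ct: df[f"marker:{ct}"].to_numpy(int)[inv].astype(bool) for ct in cts
    }
    for ct in cts:
        if not markers[ct].any():
            warnings.warn(f"cell type {ct!r} has no marker flags set", stacklevel=2)
    return ReferenceProfile(peaks, cts, R, v, markers, build)


def read_counts_tsv(
    path: str | Path, genome_build: str = "hg38", sample_meta: pd.DataFrame | None = None
) -> CountsMatrix:
    """Read a counts TSV with "chr:start-end" row ids and sample-id columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    regions = [GenomicRegion.from_id(pid) for pid in df.index]
    peaks = PeakSet(regions, genome_build)
    order = {r.id: k for k, r in enumerate(peaks)}
    perm = np.argsort(np.array([order[pid] for pid in df.index]))
    return CountsMatrix(
        df.to_numpy(float)[perm], peaks, [str(c) for c in df.columns], sample_meta
    )


def write_counts_tsv(counts: CountsMatrix, path: str | Path) -> None:
    df = pd.DataFrame(counts.values, index=list(counts.peaks.ids), columns=counts.sample_ids)
    df.to_csv(path, sep="\t", index_label="peak_id")
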