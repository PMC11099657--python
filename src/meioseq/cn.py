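"""Binned copy-number calling against a euploid normal panel.

The pipeline starts from per-bin read counts (upstream alignment keeps
uniquely mapped reads only; that contract is documented, not enforced
here).  Calling proceeds in four steps:

1. sample QC on the mapped-read fraction (< 0.90 fails);
2. bin filtering: raw counts > 1000 are overrepresented and masked;
3. normalization of each sample to 1,000,000 autosomal counts (sex
   chromosomes are scaled by the same factor but excluded from the
   denominator);
4. per-bin fold change against the normalized euploid male (40,XY)
   panel, summarized per chromosome and converted to an observed copy
   number (fold change x 2 for autosomes, x 1 for sex chromosomes,
   matching the panel's 2/1/1 reference copies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBinning

__all__ = [
    "BinnedCounts",
    "CNProfile",
    "QCResult",
    "NormalizationError",
    "MAPPED_FRACTION_THRESHOLD",
    "OVERREPRESENTED_MAX_COUNT",
    "NORMALIZATION_TARGET",
    "qc_sample",
    "filter_bins",
    "normalize",
    "fold_change",
    "observed_cn",
    "build_panel",
    "call_profile",
    "read_counts_tsv",
    "write_counts_tsv",
]

MAPPED_FRACTION_THRESHOLD = 0.90
OVERREPRESENTED_MAX_COUNT = 1000
NORMALIZATION_TARGET = 1_000_000
_REL_TOL = 1e-9  # relative tolerance on the 1M post-condition


class NormalizationError(ValueError):
    """Raised when a sample has no usable autosomal signal to anchor on."""


@dataclass
class BinnedCounts:
    """One sample's read counts over the shared genome binning.

    ``counts`` holds one value per bin of the binning; values are
    integer draws in real data but may be fractional in deterministic
    (noise-free) simulations.
    """

    sample_id: str
    counts: np.ndarray
    mapped_fraction: float | None = None
    sample_role: str = "egg"  # egg | polar_body | blastomere | panel

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError(f"sample {self.sample_id}: negative bin counts")
        if self.mapped_fraction is not None and not (0 <= self.mapped_fraction <= 1):
            raise ValueError(
                f"sample {self.sample_id}: mapped_fraction outside [0, 1]"
            )

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    status: str  # pass | fail | indeterminate
    reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class CNProfile:
    """Per-bin fold changes and per-chromosome observed copy numbers."""

    sample_id: str
    fold_change: np.ndarray  # NaN where the bin is excluded
    observed_cn: dict[str, float]
    excluded_bins: dict[int, str]  # bin index -> reason
    undefined_chromosomes: tuple[str, ...] = ()


def qc_sample(
    sample: BinnedCounts, threshold: float = MAPPED_FRACTION_THRESHOLD
) -> QCResult:
    """Fail a sample whose mapped-read fraction is below ``threshold``.

    A sample without mapped-fraction metadata is reported as
    ``indeterminate`` — never silently passed — and callers must decide
    explicitly whether to admit it.
    """
    if sample.mapped_fraction is None:
        return QCResult(sample.sample_id, "indeterminate", "mapped_fraction missing")
    if sample.mapped_fraction < threshold:
        return QCResult(
            sample.sample_id,
            "fail",
            f"mapped fraction {sample.mapped_fraction:.3f} < {threshold}",
        )
    return QCResult(sample.sample_id, "pass")


def filter_bins(
    sample: BinnedCounts, max_count: int = OVERREPRESENTED_MAX_COUNT
) -> dict[int, str]:
    """Mask overrepresented bins (raw count strictly above ``max_count``).

    Applied to raw counts before normalization.  Returns the exclusion
    map (bin index -> reason); a count exactly at the threshold is kept.
    """
    mask: dict[int, str] = {}
    for idx in np.nonzero(sample.counts > max_count)[0]:
        mask[int(idx)] = "overrepresented"
    return mask


def _excluded_array(n_bins: int, excluded: Mapping[int, str]) -> np.ndarray:
    arr = np.zeros(n_bins, dtype=bool)
    if excluded:
        arr[list(excluded)] = True
    return arr


def normalize(
    sample: BinnedCounts,
    binning: GenomeBinning,
    excluded: Mapping[int, str] | None = None,
) -> np.ndarray:
    """Scale a sample to 1,000,000 unmasked autosomal counts.

    The scale factor is anchored on autosomes only, but applied to every
    unmasked bin, autosomal and sex alike; masked bins come back NaN.
    The masked autosomal bins are likewise excluded from the denominator
    so that sample and panel are compared on the same footing.
    """
    excluded = excluded or {}
    excl = _excluded_array(binning.n_bins, excluded)
    auto = np.asarray(binning.autosome_mask())
    denom = sample.counts[auto & ~excl].sum()
    if denom <= 0:
        raise NormalizationError(
            f"sample {sample.sample_id}: no unmasked autosomal counts to normalize on"
        )
    scale = NORMALIZATION_TARGET / denom
    out = sample.counts * scale
    out[excl] = np.nan
    total = np.nansum(out[auto])
    assert abs(total - NORMALIZATION_TARGET) <= _REL_TOL * NORMALIZATION_TARGET
    return out


def fold_change(
    sample_norm: np.ndarray,
    panel_norm: np.ndarray,
    excluded: Mapping[int, str] | None = None,
) -> tuple[np.ndarray, dict[int, str]]:
    """Per-bin ratio of normalized sample to normalized panel.

    Bins where the panel has no signal cannot be ratioed and are masked
    with reason ``zero-panel`` rather than erroring; the updated
    exclusion map is returned alongside the fold changes.
    """
    if sample_norm.shape != panel_norm.shape:
        raise ValueError("sample and panel bin vectors differ in length")
    excluded = dict(excluded or {})
    fc = np.full_like(sample_norm, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = ~np.isnan(sample_norm) & ~np.isnan(panel_norm) & (panel_norm > 0)
        fc[ok] = sample_norm[ok] / panel_norm[ok]
    for idx in np.nonzero(~np.isnan(sample_norm) & (panel_norm == 0))[0]:
        excluded.setdefault(int(idx), "zero-panel")
    return fc, excluded


def observed_cn(
    fc: np.ndarray, binning: GenomeBinning
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Summarize bin fold changes into per-chromosome observed copies.

    The chromosome-level fold change is the median over its unmasked
    bins (robust to residual outlier bins), multiplied by the panel's
    reference copies: 2 for autosomes, 1 for X and Y.  Chromosomes with
    every bin masked are reported as undefined rather than given a
    value.
    """
    out: dict[str, float] = {}
    undefined: list[str] = []
    for spec in binning.chromosomes:
        idx = binning.bin_indices(spec.name)
        vals = fc[idx]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            undefined.append(spec.name)
            continue
        reference_copies = 1.0 if spec.is_sex else 2.0
        out[spec.name] = float(np.median(vals) * reference_copies)
    return out, tuple(undefined)


def build_panel(
    panel_samples: Sequence[BinnedCounts], binning: GenomeBinning
) -> np.ndarray:
    """Normalized per-bin reference from one or more euploid male samples.

    Each panel sample is bin-filtered and normalized exactly like a test
    sample; with several samples the per-bin mean of the normalized
    values is used.
    """
    if not panel_samples:
        raise ValueError("panel requires at least one sample")
    mats = []
    for sample in panel_samples:
        excl = filter_bins(sample)
        mats.append(normalize(sample, binning, excl))
    return np.nanmean(np.vstack(mats), axis=0)


def call_profile(
    sample: BinnedCounts,
    panel_norm: np.ndarray,
    binning: GenomeBinning,
    max_count: int = OVERREPRESENTED_MAX_COUNT,
) -> CNProfile:
    """Full single-sample calling: filter, normalize, ratio, summarize."""
    excluded = filter_bins(sample, max_count)
    sample_norm = normalize(sample, binning, excluded)
    fc, excluded = fold_change(sample_norm, panel_norm, excluded)
    cn, undefined = observed_cn(fc, binning)
    return CNProfile(
        sample_id=sample.sample_id,
        fold_change=fc,
        observed_cn=cn,
        excluded_bins=excluded,
        undefined_chromosomes=undefined,
    )


# ---------------------------------------------------------------------------
# on-disk formats: BED-like TSV counts + JSON QC sidecar


def write_counts_tsv(
    sample: BinnedCounts, binning: GenomeBinning, path: str | Path
) -> None:
    """Write counts as BED-like TSV (chrom, start, end, count) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(binning.bins, columns=["chrom", "start", "end"])
    counts = sample.counts
    if np.allclose(counts, np.round(counts)):
        df["count"] = np.round(counts).astype(int)
    else:
        df["count"] = counts
    df.to_csv(path, sep="\t", index=False, header=False)
    sidecar = {
        "sample_id": sample.sample_id,
        "sample_role": sample.sample_role,
        "mapped_fraction": sample.mapped_fraction,
        "total_reads": sample.total_reads,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_counts_tsv(path: str | Path, binning: GenomeBinning) -> BinnedCounts:
    """Read a BED-like counts TSV; bins must match the binning exactly."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
    )
    expected = pd.DataFrame(binning.bins, columns=["chrom", "start", "end"])
    got = df[["chrom", "start", "end"]].reset_index(drop=True)
    if len(got) != len(expected) or not (
        got["chrom"].equals(expected["chrom"])
        and got["start"].astype(int).equals(expected["start"].astype(int))
        and got["end"].astype(int).equals(expected["end"].astype(int))
    ):
        raise ValueError(f"{path}: bin intervals do not match the genome binning")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sample_id, role, mapped = path.stem, "egg", None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        sample_id = meta.get("sample_id", sample_id)
        role = meta.get("sample_role", role)
        mapped = meta.get("mapped_fraction")
    return BinnedCounts(
        sample_id=sample_id,
        counts=df["count"].to_numpy(dtype=float),
        mapped_fraction=mapped,
        sample_role=role,
    )
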