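"""Rescaled between-condition comparisons: genome-wide bins and promoters.

After depth rescaling, a uniform global loss of the mark appears as
(i) per-bin signal sitting below the diagonal despite high Pearson
correlation (the spatial distribution is preserved, only the level
drops), and (ii) fold change < 1 at nearly all gene promoters
(TSS ± flank windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    BinnedCoverage,
    EstimationError,
    FormatError,
    GenomeLayout,
)

__all__ = [
    "CorrelationResult",
    "FeatureWindows",
    "FoldChangeTrack",
    "genomewide_correlation",
    "per_bin_foldchange",
    "promoter_windows",
    "read_gene_bed",
    "window_signal",
    "sorted_promoter_foldchange",
]

DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_bins_used: int
    transform: str  # "raw" or "log2p1"


@dataclass
class FoldChangeTrack:
    """Per-bin treated/untreated ratio; ``defined`` is False where untreated == 0."""

    values: np.ndarray  # NaN where undefined
    defined: np.ndarray  # boolean mask

    @property
    def median_defined(self) -> float:
        return float(np.median(self.values[self.defined]))


@dataclass
class FeatureWindows:
    """Symmetric windows around each gene's TSS.

    ``features`` columns: gene_id, sequence, tss, strand, start, end.
    Strand locates the TSS (start of a + gene, end of a − gene, BED
    convention); the window itself is strand-symmetric and clipped to the
    sequence bounds.
    """

    features: pd.DataFrame
    flank: int


def genomewide_correlation(
    a: BinnedCoverage, b: BinnedCoverage, transform: str = "raw"
) -> CorrelationResult:
    """Pearson correlation over bins nonzero in at least one track.

    All-zero bins are uninformative padding and are excluded.  Note
    Pearson r is invariant under positive rescaling of either track, so
    this statistic is unaffected by (and does not validate) the depth
    rescaling step.
    """
    a.require_same_grid(b)
    mask = (a.values > 0) | (b.values > 0)
    x, y = a.values[mask], b.values[mask]
    if transform == "log2p1":
        x, y = np.log2(x + 1), np.log2(y + 1)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EstimationError("not enough variance to compute a correlation")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n_bins_used=int(mask.sum()), transform=transform)


def per_bin_foldchange(
    treated_rescaled: BinnedCoverage, untreated: BinnedCoverage
) -> FoldChangeTrack:
    """Per-bin ratio treated_rescaled / untreated; undefined bins flagged, not dropped."""
    treated_rescaled.require_same_grid(untreated)
    defined = untreated.values > 0
    values = np.full(len(defined), np.nan)
    values[defined] = treated_rescaled.values[defined] / untreated.values[defined]
    return FoldChangeTrack(values=values, defined=defined)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene-level BED6 annotation (chrom, start, end, gene_id, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise FormatError(f"{path}: gene annotation must be BED6, found {df.shape[1]} columns")
    out = pd.DataFrame(
        {
            "sequence": df[0],
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "gene_id": df[3],
            "strand": df[5],
        }
    )
    return out


def promoter_windows(
    annotation: pd.DataFrame, layout: GenomeLayout, flank: int = DEFAULT_FLANK
) -> FeatureWindows:
    """One TSS ± flank window per gene, clipped to sequence bounds.

    ``annotation`` needs columns sequence, start, end, gene_id, strand
    (as from :func:`read_gene_bed`).  Multi-transcript collapsing is the
    annotation provider's job; one row = one gene.
    """
    rows = []
    for rec in annotation.itertuples(index=False):
        if rec.sequence not in layout:
            raise FormatError(f"gene {rec.gene_id!r}: unknown sequence {rec.sequence!r}")
        if rec.strand == "+":
            tss = int(rec.start)
        elif rec.strand == "-":
            tss = int(rec.end)
        else:
            raise FormatError(f"gene {rec.gene_id!r}: invalid strand {rec.strand!r}")
        seqlen = layout.lengths[rec.sequence]
        rows.append(
            {
                "gene_id": rec.gene_id,
                "sequence": rec.sequence,
                "tss": tss,
                "strand": rec.strand,
                "start": max(0, tss - flank),
                "end": min(seqlen, tss + flank),
            }
        )
    return FeatureWindows(features=pd.DataFrame(rows), flank=flank)


def window_signal(track: BinnedCoverage, windows: FeatureWindows) -> np.ndarray:
    """Mean per-base signal over each window.

    Bin values are weighted by their bp overlap with the window, so the
    result equals the mean of the underlying per-base depth profile as
    represented on the grid.  Windows that are empty after clipping get
    NaN (flagged, not dropped).
    """
    grid = track.grid
    B = grid.bin_size
    out = np.full(len(windows.features), np.nan)
    for i, rec in enumerate(windows.features.itertuples(index=False)):
        s, e = int(rec.start), int(rec.end)
        if e <= s:
            continue
        off = grid.offsets[rec.sequence]
        b0, b1 = s // B, (e - 1) // B
        idx = np.arange(b0, b1 + 1)
        bin_starts = idx * B
        bin_ends = np.minimum(bin_starts + B, grid.layout.lengths[rec.sequence])
        overlap = np.minimum(bin_ends, e) - np.maximum(bin_starts, s)
        out[i] = float((track.values[off + idx] * overlap).sum() / (e - s))
    return out


def sorted_promoter_foldchange(
    treated_rescaled: BinnedCoverage,
    untreated: BinnedCoverage,
    windows: FeatureWindows,
) -> tuple[pd.DataFrame, dict]:
    """Per-promoter mean signal and fold change, sorted by descending fold change.

    Fold change is computed on window means (not averaged per-bin ratios).
    Promoters with zero untreated signal are flagged (``defined`` False)
    and sorted last, never silently dropped.  The summary reports the
    fraction of defined promoters with fold change < 1 — near 1.0 under a
    genuine global loss.
    """
    treated_rescaled.require_same_grid(untreated)
    mean_u = window_signal(untreated, windows)
    mean_t = window_signal(treated_rescaled, windows)
    defined = np.isfinite(mean_u) & np.isfinite(mean_t) & (mean_u > 0)
    fc = np.full(len(mean_u), np.nan)
    fc[defined] = mean_t[defined] / mean_u[defined]
    if not defined.any():
        raise EstimationError("no promoter with a defined fold change")
    with np.errstate(invalid="ignore", divide="ignore"):
        log2_fc = np.log2(fc)
    table = windows.features[["gene_id", "sequence", "tss", "strand"]].copy()
    table["mean_signal_untreated"] = mean_u
    table["mean_signal_treated_rescaled"] = mean_t
    table["fold_change"] = fc
    table["log2_fc"] = log2_fc
    table["defined"] = defined
    table = table.sort_values(
        ["defined", "fold_change"], ascending=[False, False], na_position="last"
    ).reset_index(drop=True)
    n_def = int(defined.sum())
    summary = {
        "n_promoters": int(len(table)),
        "n_defined": n_def,
        "fraction_below_1": float((fc[defined] < 1).sum() / n_def),
        "median_fold_change": float(np.median(fc[defined])),
    }
    return table, summary
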