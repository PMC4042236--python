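"""Partition enriched regions into bins and count normalized read quantities.

Each pre-called enriched region from either sample becomes a
:class:`BinnedRegion` carrying two aligned per-bin vectors: x1 from sample A
and x2 from sample B, counted over the *same* genomic bins so the Wilcoxon
test compares like with like.  Reads are assigned to the bin containing
their midpoint (half-open boundaries, midpoint on an edge goes right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import ConfigError, GenomicInterval, Peak
from .normalization import NormalizedTrack, quantile_normalize, sgt_adjust_counts


@dataclass
class BinnedRegion:
    """An enriched region with equal-width bins and two aligned quantity vectors."""

    region: GenomicInterval
    source_sample: str
    bins: list[GenomicInterval]
    x1: np.ndarray
    x2: np.ndarray
    name: str = ""


def partition_region(region: GenomicInterval, bin_size: int) -> list[GenomicInterval]:
    """Tile a region with ``bin_size``-bp bins; the last bin covers the
    remainder.  A region shorter than one bin becomes a single bin spanning
    the whole region."""
    if bin_size < 1:
        raise ConfigError(f"bin_size must be >= 1, got {bin_size}")
    length = region.length
    if length <= bin_size:
        return [GenomicInterval(region.chrom, region.start, region.end)]
    n_bins = math.ceil(length / bin_size)
    bins = []
    for i in range(n_bins):
        start = region.start + i * bin_size
        end = min(start + bin_size, region.end)
        bins.append(GenomicInterval(region.chrom, start, end))
    return bins


def partition_region_fixed_count(
    region: GenomicInterval, n_bins: int
) -> list[GenomicInterval]:
    """Fixed-bin-count mode: divide the region into ``n_bins`` bins of equal
    width (last bin takes the remainder); a region shorter than ``n_bins`` bp
    gets one bin per base."""
    if n_bins < 1:
        raise ConfigError(f"n_bins must be >= 1, got {n_bins}")
    n_bins = min(n_bins, region.length)
    width = math.ceil(region.length / n_bins)
    return partition_region(region, width)


def count_reads_in_bins(
    track: NormalizedTrack, bins: list[GenomicInterval]
) -> np.ndarray:
    """Sum track weights per bin by read midpoint.

    Bins must tile one region contiguously (as produced by
    :func:`partition_region`); reads outside the region contribute nothing.
    """
    out = np.zeros(len(bins), dtype=np.float64)
    if not bins:
        return out
    chrom = bins[0].chrom
    mids = track.positions.get(chrom)
    if mids is None or mids.size == 0:
        return out
    start, end = bins[0].start, bins[-1].end
    lo, hi = np.searchsorted(mids, [start, end])
    if lo == hi:
        return out
    width = bins[0].length
    idx = (mids[lo:hi] - start) // width
    np.clip(idx, 0, len(bins) - 1, out=idx)
    np.add.at(out, idx, track.weights[chrom][lo:hi])
    return out


def build_comparison_set(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    track_a: NormalizedTrack,
    track_b: NormalizedTrack,
    bin_size: int = 30,
    fixed_bin_count: int | None = None,
    neb_bin_level: bool = False,
) -> list[BinnedRegion]:
    """Bin every peak of both samples and attach aligned quantity vectors.

    Every peak becomes one BinnedRegion keeping the provenance of the
    sample whose caller found it; x2 is always counted over the identical
    genomic bins from the other sample's track.  When the tracks were
    built with the quantile method, sample B's per-bin values (pooled over
    all regions) are transformed onto sample A's bin-value distribution
    after counting.  With ``neb_bin_level`` the tracks must carry raw unit
    weights and the SGT adjustment is applied to the pooled per-bin counts
    of each sample instead of per-position multiplicities.
    """
    regions: list[BinnedRegion] = []
    for peaks, source in ((peaks_a, "A"), (peaks_b, "B")):
        for peak in peaks:
            if fixed_bin_count is not None:
                bins = partition_region_fixed_count(peak.interval, fixed_bin_count)
            else:
                bins = partition_region(peak.interval, bin_size)
            regions.append(
                BinnedRegion(
                    region=peak.interval,
                    source_sample=source,
                    bins=bins,
                    x1=count_reads_in_bins(track_a, bins),
                    x2=count_reads_in_bins(track_b, bins),
                    name=peak.name,
                )
            )
    if track_a.method == "quantile" and regions:
        reference = np.concatenate([r.x1 for r in regions])
        pooled_b = np.concatenate([r.x2 for r in regions])
        transformed = quantile_normalize(pooled_b, reference)
        offset = 0
        for r in regions:
            r.x2 = transformed[offset : offset + len(r.x2)]
            offset += len(r.x2)
    elif neb_bin_level and regions:
        for attr in ("x1", "x2"):
            pooled = np.concatenate([getattr(r, attr) for r in regions])
            adjusted = sgt_adjust_counts(pooled)
            offset = 0
            for r in regions:
                setattr(r, attr, adjusted[offset : offset + len(r.bins)])
                offset += len(r.bins)
    return regions
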