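"""Read-count normalization for two-sample ChIP-seq comparison.

Three strategies are provided, mirroring the choices a practitioner faces
when the two libraries were sequenced to different depths:

* **linear** — each read carries weight 1/S (S = total mapped reads), so
  per-bin quantities are proportions p = x/n of the library.
* **neb** — nonparametric empirical Bayes correction: the Simple
  Good-Turing (Gale–Sampson) estimator adjusts the count c of every
  distinct read position to c* using the count-of-counts spectrum, reserves
  probability mass p0 = n1/S for reads missed at finite depth, and assigns
  each distinct position the renormalized proportion
  p_c* = (1 - p0) * c* / S*  with  S* = sum_c n_c * c*.
* **quantile** — sample B's per-bin values are transformed through
  F1^-1(F2(x)) so their empirical distribution matches sample A's
  (applied at the bin level, pooled over all enriched regions).

``none`` passes raw unit-weight reads through.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .intervals import DegenerateInputError, GenomicInterval

logger = logging.getLogger(__name__)

METHODS = ("linear", "neb", "quantile", "none")


@dataclass(frozen=True)
class CountSpectrum:
    """Count-of-counts spectrum: n_c = number of distinct read positions
    observed exactly c times; depth S = sum_c c * n_c."""

    n_c: dict[int, int]
    depth: int

    def __post_init__(self) -> None:
        if any(c < 1 or n < 1 for c, n in self.n_c.items()):
            raise ValueError("spectrum requires c >= 1 and n_c >= 1")
        if self.depth != sum(c * n for c, n in self.n_c.items()):
            raise ValueError("depth S must equal sum of c * n_c")


@dataclass(frozen=True)
class SGTResult:
    """Output of the Simple Good-Turing adjustment.

    Attributes
    ----------
    c_star : dict
        Adjusted count c* for each observed count c.
    p0 : float
        Estimated total proportion of unseen reads, n1/S.
    s_star : float
        Corrected total read count, sum_c n_c * c*.
    p_star : dict
        Renormalized proportion for ONE read position observed c times:
        (1 - p0) * c* / S*.  Total mass sum_c n_c * p_c* + p0 == 1.
    """

    c_star: dict[int, float]
    p0: float
    s_star: float
    p_star: dict[int, float]


def build_count_spectrum(reads: list[GenomicInterval]) -> CountSpectrum:
    """Tally multiplicities of identical (chrom, start, end, strand) tuples."""
    position_counts = Counter(
        (r.chrom, r.start, r.end, r.strand) for r in reads
    )
    spectrum = Counter(position_counts.values())
    return CountSpectrum(dict(spectrum), depth=len(reads))


def sgt_adjust(spectrum: CountSpectrum) -> SGTResult:
    """Simple Good-Turing (Gale–Sampson) count adjustment.

    The raw Turing estimate c* = (c+1) n_{c+1} / n_c is used for small
    counts; a log-log least-squares fit of the tail (Z_c = n_c averaged
    over the gap to neighboring observed counts) supplies smoothed
    estimates, and the switch from raw to smoothed happens at the first
    count where the two differ by less than 1.65 standard deviations of
    the Turing estimate — the canonical SGT rule.  Once switched, the
    smoothed estimate is used for all larger counts.
    """
    if spectrum.depth == 0 or not spectrum.n_c:
        raise DegenerateInputError("empty spectrum: S == 0")
    S = spectrum.depth
    counts = np.array(sorted(spectrum.n_c), dtype=np.int64)
    n = np.array([spectrum.n_c[int(c)] for c in counts], dtype=np.float64)

    n1 = spectrum.n_c.get(1, 0)
    p0 = n1 / S
    if n1 == 0:
        logger.warning(
            "spectrum has no singletons (n_1 == 0): p0 set to 0; "
            "the unseen-read mass estimate is uninformative"
        )

    if len(counts) == 1:
        # A single observed count carries no frequency-of-frequency signal;
        # the count is left unadjusted.
        c = int(counts[0])
        c_star = {c: float(c)}
        slope = None
    else:
        # Z transform: spread each n_c over the gap between neighbors.
        prev = np.concatenate(([0], counts[:-1]))
        nxt = np.concatenate((counts[1:], [2 * counts[-1] - prev[-1]]))
        z = n / (0.5 * (nxt - prev))
        slope, intercept = np.polyfit(np.log(counts), np.log(z), 1)
        if slope > -1.0:
            logger.warning(
                "SGT log-log slope %.3f > -1: smoothing assumptions weak "
                "for this spectrum", slope
            )
        c_star = {}
        switched = False
        nc_map = spectrum.n_c
        for c in (int(v) for v in counts):
            smoothed = (c + 1) * ((c + 1) / c) ** slope
            if not switched:
                nc1 = nc_map.get(c + 1, 0)
                if nc1 == 0:
                    switched = True
                else:
                    nc = nc_map[c]
                    turing = (c + 1) * nc1 / nc
                    sd = math.sqrt((c + 1) ** 2 * (nc1 / nc**2) * (1 + nc1 / nc))
                    if abs(turing - smoothed) <= 1.65 * sd:
                        switched = True
            c_star[c] = smoothed if switched else turing

    s_star = float(sum(spectrum.n_c[c] * cs for c, cs in c_star.items()))
    p_star = {c: (1.0 - p0) * cs / s_star for c, cs in c_star.items()}
    return SGTResult(c_star=c_star, p0=p0, s_star=s_star, p_star=p_star)


@dataclass
class NormalizedTrack:
    """Per-position normalized read quantities for one sample.

    Positions are read midpoints grouped per chromosome (sorted), each with
    a non-negative weight on the scale of the chosen method (unit counts,
    proportions, or SGT-adjusted proportions).
    """

    method: str
    depth: int
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_reads(cls, reads: list[GenomicInterval], method: str) -> "NormalizedTrack":
        if method not in METHODS:
            raise ValueError(f"unknown normalization method {method!r}")
        depth = len(reads)
        track = cls(method=method, depth=depth)
        if method == "neb":
            position_counts = Counter(
                (r.chrom, r.start, r.end, r.strand) for r in reads
            )
            spectrum = Counter(position_counts.values())
            result = sgt_adjust(CountSpectrum(dict(spectrum), depth=depth))
            by_chrom: dict[str, list] = {}
            for (chrom, start, end, _strand), c in position_counts.items():
                by_chrom.setdefault(chrom, []).append(
                    ((start + end) // 2, result.p_star[c])
                )
        else:
            if method == "linear" and depth == 0:
                raise DegenerateInputError("cannot linear-normalize an empty sample")
            w = 1.0 / depth if method == "linear" else 1.0
            by_chrom = {}
            for r in reads:
                by_chrom.setdefault(r.chrom, []).append((r.midpoint, w))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            track.positions[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            track.weights[chrom] = np.array([w for _, w in pairs], dtype=np.float64)
        return track


def linear_normalize(counts, total: int) -> np.ndarray:
    """Proportions p = x / n for per-bin counts x and library size n."""
    if total <= 0:
        raise DegenerateInputError("total read count must be positive")
    return np.asarray(counts, dtype=np.float64) / float(total)


def neb_normalize(
    reads_a: list[GenomicInterval], reads_b: list[GenomicInterval]
) -> tuple[NormalizedTrack, NormalizedTrack]:
    """Independently SGT-adjust each sample onto a common proportion scale."""
    if not reads_a or not reads_b:
        raise DegenerateInputError("NEB normalization requires non-empty samples")
    return (
        NormalizedTrack.from_reads(reads_a, "neb"),
        NormalizedTrack.from_reads(reads_b, "neb"),
    )


def quantile_normalize(values_b, reference_a) -> np.ndarray:
    """Map sample-B values through F1^-1(F2(x)) onto A's distribution.

    Ties in B receive average ranks; the reference quantile function uses
    linear interpolation between order statistics (type-7), so the
    transform is deterministic and rank-preserving.
    """
    ref = np.asarray(reference_a, dtype=np.float64)
    if ref.size == 0:
        raise DegenerateInputError("empty reference distribution")
    b = np.asarray(values_b, dtype=np.float64)
    if b.size == 0:
        return b.copy()
    if b.size == 1:
        positions = np.array([1.0])
    else:
        positions = (rankdata(b, method="average") - 1.0) / (b.size - 1.0)
    return np.quantile(np.sort(ref), positions)


def no_normalization(values) -> np.ndarray:
    """Identity pass-through of raw values."""
    return np.asarray(values, dtype=np.float64)


def sgt_adjust_counts(values) -> np.ndarray:
    """SGT-adjust a vector of integer counts to proportions p_c*.

    Treats each vector element (e.g. a genomic bin) as one species whose
    observed count is its value; zeros carry no information and map to 0.
    Used by the bin-level NEB mode, where the count-of-counts spectrum is
    built from pooled per-bin read counts instead of per-position
    multiplicities.
    """
    arr = np.asarray(values)
    counts = np.rint(arr).astype(np.int64)
    if np.any(np.abs(arr - counts) > 1e-6) or np.any(counts < 0):
        raise ValueError("bin-level SGT requires non-negative integer counts")
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        return np.zeros(arr.shape, dtype=np.float64)
    vals, freqs = np.unique(nonzero, return_counts=True)
    spectrum = CountSpectrum(
        {int(v): int(f) for v, f in zip(vals, freqs)}, depth=int(nonzero.sum())
    )
    result = sgt_adjust(spectrum)
    out = np.zeros(arr.shape, dtype=np.float64)
    mask = counts > 0
    out[mask] = np.array([result.p_star[int(c)] for c in counts[mask]])
    return out


def reporting_scale(depth_a: int, depth_b: int, method: str) -> float:
    """Multiplier restoring count-like magnitudes to normalized proportions.

    Proportion-scale methods (linear, neb) are rescaled by the geometric
    mean of the two depths for reporting and for the difference cutoff d;
    count-scale methods (none, quantile) use scale 1.
    """
    if method in ("linear", "neb"):
        return math.sqrt(float(depth_a) * float(depth_b))
    return 1.0
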