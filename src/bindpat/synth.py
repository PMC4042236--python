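"""Synthetic two-sample ChIP-seq data with planted ground-truth patterns.

The generator emulates the inputs the comparison pipeline consumes: two
read samples of (possibly different) sequencing depth, uniform background
noise, rectangular enriched regions emitting reads at a fold over
background with per-region Poisson counts, pre-called peak BED files
containing exactly the planted spans, and a gene annotation placed so
every planted peak has a designated gene within the association distance.
An optional PCR-duplication step resamples existing read positions so the
count-of-counts spectrum has non-trivial multiplicities (n_2, n_3 > 0),
exercising the Good-Turing adjustment.

Reads are fixed-width tags (36 bp by default, typical early-Illumina
length); enrichment profiles are rectangular, which is sufficient for rank
tests that only use per-bin order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import ConfigError, GeneRecord, GenomicInterval, Peak

PATTERNS = ("Only_A", "Only_B", "Shift", "Unchanged", "Null")


@dataclass(frozen=True)
class PlannedPeak:
    """One planted configuration.

    For ``Only_A``/``Only_B``/``Null`` a single span [start, start+width)
    carries fold_a in sample A and fold_b in sample B.  For ``Shift`` and
    ``Unchanged`` the A-enriched span sits at ``start`` and the B-enriched
    span at ``start + offset`` (same width); the offset must be <= 1 kb for
    Unchanged and in (1 kb, 100 kb] for Shift.
    """

    chrom: str
    start: int
    width: int
    pattern: str
    fold_a: float = 1.0
    fold_b: float = 1.0
    offset: int = 0


@dataclass
class SimulationConfig:
    seed: int
    chrom_lengths: dict[str, int]
    depth_a: int
    depth_b: int
    background_rate: float  # expected-mass units per bp, before depth scaling
    peak_plan: list[PlannedPeak] = field(default_factory=list)
    read_length: int = 36
    duplication_rate: float = 0.0
    gene_offset: int = 3_000  # designated gene placed this far 3' of the A span
    gene_length: int = 2_000
    n_extra_genes: int = 0  # filler genes in a desert past the last peak

    def validate(self) -> None:
        if self.depth_a <= 0 or self.depth_b <= 0:
            raise ConfigError("depths must be positive")
        if self.background_rate <= 0:
            raise ConfigError("background_rate must be positive")
        for peak in self.peak_plan:
            if peak.pattern not in PATTERNS:
                raise ConfigError(f"unknown pattern {peak.pattern!r}")
            if peak.chrom not in self.chrom_lengths:
                raise ConfigError(f"peak on unknown chromosome {peak.chrom}")
            if peak.width <= self.read_length:
                raise ConfigError("peak width must exceed the read length")
            end = peak.start + peak.width
            if peak.pattern in ("Shift", "Unchanged"):
                end = max(end, peak.start + peak.offset + peak.width)
            if peak.start < 0 or end > self.chrom_lengths[peak.chrom]:
                raise ConfigError(
                    f"planted peak at {peak.chrom}:{peak.start} exceeds bounds"
                )
            if peak.pattern == "Shift" and not (1_000 < peak.offset <= 100_000):
                raise ConfigError("Shift offset must be in (1 kb, 100 kb]")
            if peak.pattern == "Unchanged" and not (0 <= peak.offset <= 1_000):
                raise ConfigError("Unchanged offset must be <= 1 kb")


def _sample_spans(config: SimulationConfig) -> dict[str, list[tuple[PlannedPeak, int, float]]]:
    """Per sample: (plan entry, span start, fold) for every emitting span."""
    spans: dict[str, list[tuple[PlannedPeak, int, float]]] = {"A": [], "B": []}
    for peak in config.peak_plan:
        if peak.pattern in ("Shift", "Unchanged"):
            if peak.fold_a > 1.0:
                spans["A"].append((peak, peak.start, peak.fold_a))
            if peak.fold_b > 1.0:
                spans["B"].append((peak, peak.start + peak.offset, peak.fold_b))
        else:
            if peak.fold_a > 1.0:
                spans["A"].append((peak, peak.start, peak.fold_a))
            if peak.fold_b > 1.0:
                spans["B"].append((peak, peak.start, peak.fold_b))
    return spans


def _emit_sample(
    config: SimulationConfig,
    spans: list[tuple[PlannedPeak, int, float]],
    depth: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    rate = config.background_rate
    genome = sum(config.chrom_lengths.values())
    total_mass = rate * genome + sum(
        (fold - 1.0) * rate * p.width for p, _, fold in spans
    )
    scaling = depth / total_mass
    reads: list[tuple[str, int]] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_bg = rng.poisson(rate * length * scaling)
        hi = max(1, length - config.read_length)
        starts = rng.integers(0, hi, size=n_bg)
        reads.extend((chrom, int(s)) for s in starts)
    for peak, span_start, fold in spans:
        n_peak = rng.poisson((fold - 1.0) * rate * peak.width * scaling)
        hi = span_start + peak.width - config.read_length
        starts = rng.integers(span_start, max(span_start + 1, hi), size=n_peak)
        reads.extend((peak.chrom, int(s)) for s in starts)
    if config.duplication_rate > 0.0 and len(reads) > 1:
        n_dup = rng.binomial(len(reads), config.duplication_rate)
        targets = rng.choice(len(reads), size=n_dup, replace=False)
        sources = rng.integers(0, len(reads), size=n_dup)
        for t, s in zip(targets, sources):
            reads[t] = reads[s]
    strands = rng.integers(0, 2, size=len(reads))
    intervals = [
        GenomicInterval(chrom, start, start + config.read_length,
                        "+" if strand == 0 else "-")
        for (chrom, start), strand in zip(reads, strands)
    ]
    intervals.sort(key=lambda r: (r.chrom, r.start, r.strand))
    return intervals


def generate_dataset(config: SimulationConfig):
    """Generate (reads_a, reads_b, peaks_a, peaks_b, genes, truth_table).

    The truth table is a list of dicts, one per plan entry, recording the
    planted spans, folds, intended pattern and designated gene.  Identical
    seed and config yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spans = _sample_spans(config)
    reads_a = _emit_sample(config, spans["A"], config.depth_a, rng)
    reads_b = _emit_sample(config, spans["B"], config.depth_b, rng)

    peaks_a = [
        Peak(GenomicInterval(p.chrom, start, start + p.width), "A", f"peak_{i}")
        for i, (p, start, _fold) in enumerate(spans["A"])
    ]
    peaks_b = [
        Peak(GenomicInterval(p.chrom, start, start + p.width), "B", f"peak_{i}")
        for i, (p, start, _fold) in enumerate(spans["B"])
    ]

    genes: list[GeneRecord] = []
    truth = []
    last_end = 0
    for i, peak in enumerate(config.peak_plan):
        gene = None
        if peak.pattern != "Null":
            gstart = peak.start + peak.width + config.gene_offset
            gend = gstart + config.gene_length
            if gend > config.chrom_lengths[peak.chrom]:
                gend = peak.start - config.gene_offset
                gstart = gend - config.gene_length
            gene = GeneRecord(f"GENE{i}", GenomicInterval(peak.chrom, gstart, gend, "+"))
            genes.append(gene)
        b_start = (
            peak.start + peak.offset
            if peak.pattern in ("Shift", "Unchanged")
            else peak.start
        )
        truth.append(
            {
                "id": f"plan_{i}",
                "chrom": peak.chrom,
                "a_start": peak.start,
                "a_end": peak.start + peak.width,
                "b_start": b_start,
                "b_end": b_start + peak.width,
                "pattern": peak.pattern,
                "gene": gene.name if gene else "NA",
                "fold_a": peak.fold_a,
                "fold_b": peak.fold_b,
            }
        )
        last_end = max(last_end, b_start + peak.width)
    for j in range(config.n_extra_genes):
        chrom = sorted(config.chrom_lengths)[-1]
        gstart = last_end + 150_000 + j * (config.gene_length + 5_000)
        gend = gstart + config.gene_length
        if gend > config.chrom_lengths[chrom]:
            break
        genes.append(GeneRecord(f"FILLER{j}", GenomicInterval(chrom, gstart, gend, "+")))
    return reads_a, reads_b, peaks_a, peaks_b, genes, truth


def depth_imbalance_scenario(
    base_config: SimulationConfig, imbalance_factor: float
) -> SimulationConfig:
    """Same plan, sample B sequenced ``imbalance_factor`` times shallower."""
    if imbalance_factor < 1.0:
        raise ConfigError("imbalance_factor must be >= 1")
    return replace(base_config, depth_b=int(round(base_config.depth_a / imbalance_factor)))


def write_dataset(outdir: str, reads_a, reads_b, peaks_a, peaks_b, genes, truth) -> dict:
    """Write the dataset as BED files plus a truth TSV; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reads_a": os.path.join(outdir, "reads_A.bed"),
        "reads_b": os.path.join(outdir, "reads_B.bed"),
        "peaks_a": os.path.join(outdir, "peaks_A.bed"),
        "peaks_b": os.path.join(outdir, "peaks_B.bed"),
        "genes": os.path.join(outdir, "genes.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    for key, reads in (("reads_a", reads_a), ("reads_b", reads_b)):
        with open(paths[key], "w") as fh:
            for r in reads:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")
    for key, peaks in (("peaks_a", peaks_a), ("peaks_b", peaks_b)):
        with open(paths[key], "w") as fh:
            for p in peaks:
                iv = p.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\n")
    with open(paths["genes"], "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.name}\t0\t{iv.strand}\n")
    columns = [
        "id", "chrom", "a_start", "a_end", "b_start", "b_end",
        "pattern", "gene", "fold_a", "fold_b",
    ]
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
    return paths


def pattern_recovery_config(
    seed: int = 0,
    n_each: int = 15,
    fold: float = 8.0,
    width: int = 300,
    depth: int = 200_000,
    unchanged_offset: int = 400,
    shift_offset: int = 5_000,
    spacing: int = 250_000,
    duplication_rate: float = 0.15,
) -> SimulationConfig:
    """Planted-truth study: n_each peaks of each non-Null pattern class,
    spaced far enough apart that designated genes never link distinct
    plan entries (spacing >> 2 * association distance is not required;
    spacing > association distance + max offset suffices)."""
    plan = []
    cursor = 50_000
    chrom = "chr1"
    for k in range(n_each):
        for pattern in ("Only_A", "Only_B", "Shift", "Unchanged"):
            if pattern == "Only_A":
                entry = PlannedPeak(chrom, cursor, width, pattern, fold_a=fold)
            elif pattern == "Only_B":
                entry = PlannedPeak(chrom, cursor, width, pattern, fold_b=fold)
            elif pattern == "Shift":
                entry = PlannedPeak(
                    chrom, cursor, width, pattern,
                    fold_a=fold, fold_b=fold, offset=shift_offset,
                )
            else:
                entry = PlannedPeak(
                    chrom, cursor, width, pattern,
                    fold_a=fold, fold_b=fold, offset=unchanged_offset,
                )
            plan.append(entry)
            cursor += spacing
    return SimulationConfig(
        seed=seed,
        chrom_lengths={chrom: cursor + 200_000},
        depth_a=depth,
        depth_b=depth,
        background_rate=0.002,
        peak_plan=plan,
        duplication_rate=duplication_rate,
    )


def null_config(
    seed: int = 0,
    n_regions: int = 2_000,
    fold: float = 5.0,
    width: int = 300,
    depth: int = 300_000,
    spacing: int = 1_500,
) -> SimulationConfig:
    """All-Null plan: every span equally enriched in both samples, so any
    DER called downstream is a false positive."""
    plan = []
    cursor = 2_000
    chrom = "chr1"
    for _ in range(n_regions):
        plan.append(PlannedPeak(chrom, cursor, width, "Null", fold_a=fold, fold_b=fold))
        cursor += spacing
    return SimulationConfig(
        seed=seed,
        chrom_lengths={chrom: cursor + 400_000},
        depth_a=depth,
        depth_b=depth,
        background_rate=0.002,
        peak_plan=plan,
        duplication_rate=0.1,
        n_extra_genes=2,
    )
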