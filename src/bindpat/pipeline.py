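"""End-to-end comparison pipeline: normalize, bin, test, call, classify, write.

The single entry point :func:`run_compare` wires the modules together in
the order the method prescribes and writes all outputs to one directory:
per-sample DER BED files, per-sample wiggle tracks, a pattern TSV, a
summary report, the effective configuration (YAML) and a run log.  Output
is deterministic for fixed inputs and configuration (no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import io_formats
from .binning import build_comparison_set
from .differential import Cutoffs, call_ders
from .intervals import BindpatError, ConfigError
from .normalization import METHODS, NormalizedTrack, reporting_scale
from .patterns import (
    DEFAULT_MAX_GENE_DISTANCE,
    DEFAULT_SHIFT_THRESHOLD,
    associate_genes,
    classify_patterns,
    pattern_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one comparison run.

    Defaults follow the method's reference parameterization: 30-bp bins,
    one-sided p < 0.05, ratio 1.2, difference 0.8, paired signed-rank
    test, gene association within 100 kb and a 1-kb Shift threshold.
    """

    reads_a: str = ""
    reads_b: str = ""
    peaks_a: str = ""
    peaks_b: str = ""
    genes: str = ""
    outdir: str = "bindpat_out"
    normalization: str = "neb"
    neb_level: str = "read"  # 'read' (per-position multiplicities) or 'bin'
    bin_size: int = 30
    fixed_bin_count: int | None = None
    test: str = "signed_rank"
    alpha: float = 0.05
    ratio_min: float = 1.2
    diff_min: float = 0.8
    shift_threshold: int = DEFAULT_SHIFT_THRESHOLD
    max_gene_distance: int = DEFAULT_MAX_GENE_DISTANCE
    partner_metric: str = "center"
    gene_format: str = "bed"
    correction: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if self.normalization not in METHODS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.test not in ("signed_rank", "rank_sum"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        if self.neb_level not in ("read", "bin"):
            raise ConfigError("neb_level must be 'read' or 'bin'")
        for key in ("reads_a", "reads_b", "peaks_a", "peaks_b", "genes"):
            path = getattr(self, key)
            if not path or not os.path.exists(path):
                raise ConfigError(f"input file for {key!r} missing: {path!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunResult:
    """In-memory results of a comparison run (also serialized to outdir)."""

    comparison_set: list
    ders: list
    calls: list
    intergenic: list
    counts: dict
    outputs: dict[str, str] = field(default_factory=dict)


def run_compare(config: RunConfig) -> RunResult:
    """Execute the full two-sample comparison; see module docstring."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    outputs = {
        "ders_a": os.path.join(config.outdir, "ders_A.bed"),
        "ders_b": os.path.join(config.outdir, "ders_B.bed"),
        "wig_a": os.path.join(config.outdir, "track_A.wig"),
        "wig_b": os.path.join(config.outdir, "track_B.wig"),
        "patterns": os.path.join(config.outdir, "patterns.tsv"),
        "summary": os.path.join(config.outdir, "summary.tsv"),
        "config": os.path.join(config.outdir, "config.yaml"),
        "log": os.path.join(config.outdir, "run.log"),
    }
    log_lines: list[str] = []

    def stage(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        reads_a = io_formats.read_reads_bed(config.reads_a)
        reads_b = io_formats.read_reads_bed(config.reads_b)
        stage(f"input: {len(reads_a)} reads (A), {len(reads_b)} reads (B)")
        peaks_a = io_formats.read_peaks_bed(config.peaks_a, "A")
        peaks_b = io_formats.read_peaks_bed(config.peaks_b, "B")
        stage(f"input: {len(peaks_a)} peaks (A), {len(peaks_b)} peaks (B)")
        genes = io_formats.read_genes(config.genes, config.gene_format)
        if not genes:
            raise ConfigError("gene annotation is empty; patterns undefined")
        stage(f"input: {len(genes)} gene records")

        neb_bin_level = config.normalization == "neb" and config.neb_level == "bin"
        track_method = "none" if neb_bin_level else config.normalization
        track_a = NormalizedTrack.from_reads(reads_a, track_method)
        track_b = NormalizedTrack.from_reads(reads_b, track_method)
        scale = reporting_scale(len(reads_a), len(reads_b), config.normalization)
        stage(f"normalization: {config.normalization} (reporting scale {scale:.6g})")

        comparison = build_comparison_set(
            peaks_a, peaks_b, track_a, track_b,
            bin_size=config.bin_size, fixed_bin_count=config.fixed_bin_count,
            neb_bin_level=neb_bin_level,
        )
        stage(f"binning: {len(comparison)} regions at bin_size={config.bin_size}")

        cutoffs = Cutoffs(
            alpha=config.alpha,
            ratio_min=config.ratio_min,
            diff_min=config.diff_min,
            paired=(config.test == "signed_rank"),
            correction=config.correction,
        )
        all_regions = call_ders(comparison, cutoffs, scale=scale)
        ders = [dr for dr in all_regions if dr.enriched_in is not None]
        ders_a = [dr for dr in ders if dr.enriched_in == "A"]
        ders_b = [dr for dr in ders if dr.enriched_in == "B"]
        stage(
            f"testing: {len(all_regions)} regions -> "
            f"{len(ders_a)} A-DERs, {len(ders_b)} B-DERs"
        )

        associations = associate_genes(ders, genes, config.max_gene_distance)
        calls, intergenic = classify_patterns(
            ders_a, ders_b, associations,
            shift_threshold=config.shift_threshold,
            partner_metric=config.partner_metric,
        )
        counts = pattern_counts(calls, intergenic)
        stage(
            "patterns: "
            + ", ".join(
                f"{s} {lbl}={counts[s][lbl]}"
                for s in ("A", "B")
                for lbl in ("Only", "Shift", "Unchanged", "Intergenic")
            )
        )

        io_formats.write_der_bed(
            [c for c in calls if c.der.enriched_in == "A"], outputs["ders_a"]
        )
        io_formats.write_der_bed(
            [c for c in calls if c.der.enriched_in == "B"], outputs["ders_b"]
        )
        io_formats.write_wiggle(
            [dr.binned for dr in all_regions if dr.binned.source_sample == "A"],
            "A", outputs["wig_a"],
        )
        io_formats.write_wiggle(
            [dr.binned for dr in all_regions if dr.binned.source_sample == "B"],
            "B", outputs["wig_b"],
        )
        _write_patterns_tsv(calls, intergenic, outputs["patterns"])
        io_formats.write_summary_report(config.to_dict(), counts, outputs["summary"])
        with open(outputs["config"], "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        with open(outputs["log"], "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except BindpatError:
        io_formats.remove_if_exists(outputs.values())
        raise
    return RunResult(
        comparison_set=comparison,
        ders=ders,
        calls=calls,
        intergenic=intergenic,
        counts=counts,
        outputs=outputs,
    )


def _write_patterns_tsv(calls, intergenic, path: str) -> None:
    header = [
        "chrom", "start", "end", "sample", "pattern", "gene",
        "p_value", "ratio", "difference", "partner_distance",
    ]
    rows = []
    for call in calls:
        region = call.der.binned.region
        rows.append(
            (
                region.chrom, region.start, region.end,
                call.der.binned.source_sample, call.pattern,
                call.gene.name if call.gene else "NA",
                f"{call.der.p_value:.6g}", f"{call.der.r:.6g}",
                f"{call.der.d:.6g}",
                "NA" if call.partner_distance is None
                else f"{call.partner_distance:.6g}",
            )
        )
    for der in intergenic:
        region = der.binned.region
        rows.append(
            (
                region.chrom, region.start, region.end,
                der.binned.source_sample, "Intergenic", "NA",
                f"{der.p_value:.6g}", f"{der.r:.6g}", f"{der.d:.6g}", "NA",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
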