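"""Readers and writers for the genomic text formats the pipeline consumes.

Input: BED3/BED6 reads and peaks, BED6 or refGene-style gene annotations,
optionally BAM via a thin pysam adapter.  Output: DER BED, wiggle
(variableStep) tracks and a TSV summary report.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

from .intervals import ConfigError, GeneRecord, GenomicInterval, ParseError, Peak

_SKIP_PREFIXES = ("#", "track", "browser")


def _bed_lines(path: str):
    """Yield (line_number, fields) for data lines of a BED-like file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_coords(fields: Sequence[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_reads_bed(path: str) -> list[GenomicInterval]:
    """Read aligned reads from a BED file (one interval per mapped read).

    Track/browser/comment lines are skipped; an empty file yields an empty
    list.  Malformed coordinates raise :class:`ParseError` naming the line.
    """
    return [_parse_coords(fields, lineno, path) for lineno, fields in _bed_lines(path)]


def read_reads_bam(path: str) -> list[GenomicInterval]:
    """Adapter: convert mapped BAM alignments to intervals.

    Each mapped alignment becomes (reference, pos, pos + aligned length,
    strand).  Unmapped records are skipped.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            end = aln.reference_end or aln.reference_start + aln.query_length
            strand = "-" if aln.is_reverse else "+"
            reads.append(
                GenomicInterval(aln.reference_name, aln.reference_start, end, strand)
            )
    return reads


def read_peaks_bed(path: str, sample_label: str) -> list[Peak]:
    """Read pre-called enriched regions, tagging each with its sample label.

    Overlapping or duplicate peaks are preserved as-is (no merging, no
    dedup); a 4th BED column, when present, is kept as the region name.
    """
    peaks = []
    for lineno, fields in _bed_lines(path):
        interval = _parse_coords(fields, lineno, path)
        name = fields[3] if len(fields) >= 4 else ""
        peaks.append(Peak(interval, sample_label, name))
    return peaks


def read_genes(path: str, format: str = "bed") -> list[GeneRecord]:
    """Read a gene annotation.

    ``format='bed'`` expects BED with >=4 columns (name required; strand from
    column 6, '+' assumed when absent).  ``format='refgene'`` expects
    tab-separated (name, chrom, strand, txStart, txEnd), optionally preceded
    by a numeric bin column as in UCSC refGene dumps.  Rows sharing a gene
    name (isoforms) are all kept.
    """
    if format not in ("bed", "refgene"):
        raise ConfigError(f"unknown gene annotation format {format!r}")
    genes = []
    for lineno, fields in _bed_lines(path):
        if format == "bed":
            if len(fields) < 4 or not fields[3]:
                raise ParseError(f"{path}:{lineno}: gene name (column 4) required")
            interval = _parse_coords(fields, lineno, path)
            if interval.strand == ".":
                interval = GenomicInterval(
                    interval.chrom, interval.start, interval.end, "+"
                )
            genes.append(GeneRecord(fields[3], interval))
        else:
            row = fields
            if row and row[0].isdigit() and len(row) >= 6:
                row = row[1:]
            if len(row) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 refGene fields")
            name, chrom, strand = row[0], row[1], row[2]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or invalid strand")
            try:
                start, end = int(row[3]), int(row[4])
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneRecord(name, interval))
    return genes


def bed_score(p_value: float) -> int:
    """-10*log10(p), clamped to [0, 1000] and rounded to an integer."""
    if p_value <= 0:
        return 1000
    return int(round(min(1000.0, max(0.0, -10.0 * math.log10(p_value)))))


def write_der_bed(calls: Iterable, path: str) -> None:
    """Write differential enriched regions as BED6.

    ``calls`` are PatternCall objects (see module ``patterns``).  The name
    column encodes ``pattern|gene``; the score column encodes
    -10*log10(p) clamped to [0, 1000].
    """
    rows = []
    for call in calls:
        der = call.der
        region = der.binned.region
        gene = call.gene.name if call.gene is not None else "NA"
        rows.append(
            (
                region.chrom,
                region.start,
                region.end,
                f"{call.pattern}|{gene}",
                bed_score(der.p_value),
                region.strand,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _fmt_value(v: float) -> str:
    return f"{v:.6g}"


def write_wiggle(binned_regions: Iterable, sample: str, path: str) -> None:
    """Write per-bin normalized quantities as a variableStep wiggle track.

    ``sample`` selects which vector is emitted ('A' -> x1, 'B' -> x2).
    Positions are 1-based (wiggle convention); a new variableStep
    declaration is emitted whenever the chromosome or the span (bin width)
    changes, so the short final bin of a region gets its own block.
    """
    if sample not in ("A", "B"):
        raise ConfigError("sample must be 'A' or 'B'")
    regions = sorted(binned_regions, key=lambda b: (b.region.chrom, b.region.start))
    with open(path, "w") as fh:
        current = (None, None)  # (chrom, span)
        for br in regions:
            values = br.x1 if sample == "A" else br.x2
            for bin_iv, value in zip(br.bins, values):
                key = (bin_iv.chrom, bin_iv.length)
                if key != current:
                    fh.write(
                        f"variableStep chrom={bin_iv.chrom} span={bin_iv.length}\n"
                    )
                    current = key
                fh.write(f"{bin_iv.start + 1} {_fmt_value(float(value))}\n")


def write_summary_report(run_config, pattern_counts: dict, path: str) -> None:
    """Write the run summary: configuration echo plus per-sample pattern counts.

    ``pattern_counts`` maps sample label -> {pattern label -> count}; the
    label set always includes Only/Shift/Unchanged (zeros emitted).
    """
    labels = ["Only", "Shift", "Unchanged", "Intergenic"]
    with open(path, "w") as fh:
        fh.write("# bindpat run summary\n")
        for key, value in sorted(run_config.items()):
            fh.write(f"# {key}: {value}\n")
        fh.write("sample\tpattern\tcount\n")
        for sample in sorted(pattern_counts):
            counts = pattern_counts[sample]
            for label in labels:
                fh.write(f"{sample}\t{label}\t{counts.get(label, 0)}\n")


def remove_if_exists(paths: Iterable[str]) -> None:
    for p in paths:
        if os.path.exists(p):
            os.remove(p)
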