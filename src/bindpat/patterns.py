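"""Gene association and Only/Shift/Unchanged pattern classification.

A DER is associated with every annotated gene within 100 kb (edge gap;
distance 0 when overlapping).  Each gene-associated DER is then labelled:

* **Only** — no DER in the other sample shares any of its genes;
* **Unchanged** — its nearest gene-sharing partner in the other sample is
  within 1 kb;
* **Shift** — that partner is more than 1 kb away.

DERs with no gene within range are reported separately as intergenic; the
three-way classification is gene-anchored by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .differential import DifferentialRegion
from .intervals import ConfigError, GeneRecord

DEFAULT_MAX_GENE_DISTANCE = 100_000
DEFAULT_SHIFT_THRESHOLD = 1_000


@dataclass(frozen=True)
class GeneAssociation:
    """A DER linked to a gene within the association distance."""

    der: DifferentialRegion
    gene: GeneRecord
    distance: int


@dataclass
class PatternCall:
    """A DER with its binding-pattern label and supporting evidence."""

    der: DifferentialRegion
    pattern: str  # 'Only' | 'Shift' | 'Unchanged'
    gene: GeneRecord | None
    partner: DifferentialRegion | None = None
    partner_distance: float | None = None


def _region_of(der: DifferentialRegion):
    return der.binned.region


def associate_genes(
    ders: list[DifferentialRegion],
    genes: list[GeneRecord],
    max_dist: int = DEFAULT_MAX_GENE_DISTANCE,
) -> list[GeneAssociation]:
    """Associate every DER with every gene within ``max_dist`` bp.

    Distance is 0 for overlap, otherwise the gap between nearest edges.
    A DER may carry several associations (and a gene several DERs).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.interval.chrom, []).append(gene)
    associations = []
    for der in ders:
        region = _region_of(der)
        for gene in by_chrom.get(region.chrom, ()):
            dist = region.gap_to(gene.interval)
            if dist <= max_dist:
                associations.append(GeneAssociation(der, gene, dist))
    return associations


def _sort_key(der: DifferentialRegion):
    region = _region_of(der)
    return (region.chrom, region.start, region.end)


def _partner_distance(a, b, metric: str) -> float:
    ra, rb = _region_of(a), _region_of(b)
    if metric == "center":
        return abs(ra.center - rb.center)
    return float(ra.gap_to(rb))


def classify_patterns(
    ders_a: list[DifferentialRegion],
    ders_b: list[DifferentialRegion],
    associations: list[GeneAssociation],
    shift_threshold: int = DEFAULT_SHIFT_THRESHOLD,
    partner_metric: str = "center",
) -> tuple[list[PatternCall], list[DifferentialRegion]]:
    """Label every gene-associated DER Only, Shift or Unchanged.

    For each DER the candidate partners are the DERs of the *other* sample
    sharing at least one associated gene (gene identity is the gene name,
    so isoform rows collapse).  No partner -> Only.  Otherwise the nearest
    partner (center-to-center by default; ties broken by smaller start,
    then chromosome) decides: distance <= ``shift_threshold`` ->
    Unchanged, else Shift.  Returns (pattern calls, intergenic DERs).
    """
    if partner_metric not in ("center", "edge"):
        raise ConfigError(f"unknown partner metric {partner_metric!r}")

    genes_of: dict[int, dict[str, GeneAssociation]] = {}
    for assoc in associations:
        slot = genes_of.setdefault(id(assoc.der), {})
        prev = slot.get(assoc.gene.name)
        if prev is None or assoc.distance < prev.distance:
            slot[assoc.gene.name] = assoc

    by_gene: dict[tuple[str, str], list[DifferentialRegion]] = {}
    for sample, ders in (("A", ders_a), ("B", ders_b)):
        for der in ders:
            for gene_name in genes_of.get(id(der), {}):
                by_gene.setdefault((sample, gene_name), []).append(der)

    calls: list[PatternCall] = []
    intergenic: list[DifferentialRegion] = []
    for sample, other, ders in (("A", "B", ders_a), ("B", "A", ders_b)):
        for der in sorted(ders, key=_sort_key):
            gene_assocs = genes_of.get(id(der))
            if not gene_assocs:
                intergenic.append(der)
                continue
            nearest_gene = min(
                gene_assocs.values(), key=lambda a: (a.distance, a.gene.name)
            ).gene
            partners = {
                id(p): p
                for gene_name in gene_assocs
                for p in by_gene.get((other, gene_name), ())
            }
            if not partners:
                calls.append(PatternCall(der, "Only", nearest_gene))
                continue
            partner = min(
                partners.values(),
                key=lambda p: (
                    _partner_distance(der, p, partner_metric),
                    _region_of(p).start,
                    _region_of(p).chrom,
                ),
            )
            dist = _partner_distance(der, partner, partner_metric)
            label = "Unchanged" if dist <= shift_threshold else "Shift"
            calls.append(PatternCall(der, label, nearest_gene, partner, dist))
    return calls, intergenic


def pattern_counts(
    calls: list[PatternCall], intergenic: list[DifferentialRegion]
) -> dict[str, dict[str, int]]:
    """Tally pattern labels per sample (shape of the summary report)."""
    counts: dict[str, dict[str, int]] = {
        "A": {"Only": 0, "Shift": 0, "Unchanged": 0, "Intergenic": 0},
        "B": {"Only": 0, "Shift": 0, "Unchanged": 0, "Intergenic": 0},
    }
    for call in calls:
        counts[call.der.binned.source_sample][call.pattern] += 1
    for der in intergenic:
        counts[der.binned.source_sample]["Intergenic"] += 1
    return counts
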