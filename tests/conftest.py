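import pytest

from bindpat import GeneRecord, GenomicInterval, Peak


@pytest.fixture
def bed_writer(tmp_path):
    """Write tab-joined rows to a temp BED file and return its path."""

    def write(rows, name="test.bed"):
        path = tmp_path / name
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return str(path)

    return write


@pytest.fixture
def simple_genes():
    return [
        GeneRecord("GENE1", GenomicInterval("chr1", 5_000, 9_000, "+")),
        GeneRecord("GENE2", GenomicInterval("chr1", 400_000, 404_000, "-")),
        GeneRecord("GENE3", GenomicInterval("chr2", 10_000, 14_000, "+")),
    ]


@pytest.fixture
def peak():
    def make(chrom="chr1", start=100, end=400, sample="A", name=""):
        return Peak(GenomicInterval(chrom, start, end), sample, name)

    return make
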