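import pytest

from nease.annotation_io import AnnotationUniverse, GeneList


@pytest.fixture
def toy_universe() -> AnnotationUniverse:
    """Ten-gene background with one five-gene term and assorted overlaps."""
    return AnnotationUniverse(
        "toy",
        {
            "A": {"g1", "g2", "g3", "g4", "g5"},
            "B": {"g4", "g5", "g6", "g7", "g8"},
            "C": {"g9", "g10"},
        },
    )


@pytest.fixture
def toy_list() -> GeneList:
    return GeneList.from_iterable(["g1", "g2", "g3"])


def gaf_line(gene: str, go_id: str, aspect: str, qualifier: str = "") -> str:
    """One synthetic 17-column GAF 2.2 association line."""
    fields = [""] * 17
    fields[0] = "DB"
    fields[1] = gene
    fields[2] = gene
    fields[3] = qualifier
    fields[4] = go_id
    fields[5] = "PMID:1"
    fields[6] = "IEA"
    fields[8] = aspect
    fields[9] = f"name of {go_id}"
    fields[11] = "protein"
    fields[12] = "taxon:9606"
    fields[13] = "20200101"
    fields[14] = "DB"
    return "\t".join(fields)


@pytest.fixture
def gaf_file(tmp_path):
    """Six-association GAF fixture spanning aspects P and F, one NOT line."""
    lines = [
        "!gaf-version: 2.2",
        gaf_line("g1", "GO:0007049", "P"),
        gaf_line("g2", "GO:0007049", "P"),
        gaf_line("g3", "GO:0006915", "P"),
        gaf_line("g4", "GO:0006915", "P", qualifier="NOT|involved_in"),
        gaf_line("g1", "GO:0005515", "F"),
        gaf_line("g5", "GO:0005515", "F"),
    ]
    path = tmp_path / "toy.gaf"
    path.write_text("\n".join(lines) + "\n")
    return path
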