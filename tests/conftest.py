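import pytest

from mitoskew.annotation import (
    Feature,
    GenomeAnnotation,
    load_example_annotation,
)


@pytest.fixture(scope="session")
def example():
    """The bundled Asotana magnifica organisation table."""
    return load_example_annotation()


@pytest.fixture()
def toy_two_gene():
    """Two abutting-ish plus-strand genes on a 100 bp circular genome."""
    return GenomeAnnotation(
        organism="toy", length=100, features=[
            Feature("cox1", "PCG", 1, 30, "+"),
            Feature("cox2", "PCG", 41, 70, "+"),
        ],
    )


def make_genbank(ann: GenomeAnnotation, sequence: str | None = None) -> str:
    """Serialise an annotation to GenBank text via Biopython (test helper;
    the package itself only reads GenBank)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    seq = sequence if sequence is not None else "N" * ann.length
    rec = SeqRecord(Seq(seq), id="TEST00000001", name="TEST00000001",
                    description=ann.organism)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if ann.circular else "linear"
    rec.annotations["organism"] = ann.organism
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    for f in ann.features:
        strand = {"+": 1, "-": -1, None: None}[f.strand]
        if f.wraps_origin:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, ann.length, strand),
                SimpleLocation(0, f.end, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        rec.features.append(SeqFeature(loc, type=type_of[f.category],
                                       qualifiers={"gene": [f.name]}))
    import io

    from Bio import SeqIO

    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()
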