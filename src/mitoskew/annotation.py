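"""Reading, writing and slicing annotated circular mitogenomes.

Coordinates are 1-based inclusive at every interface, matching the
conventions of published mitogenome organisation tables.  Features on the
minus strand keep their plus-strand coordinates (``start <= end``); a
feature spanning the origin of a circular genome sets ``wraps_origin``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "GenomeAnnotation",
    "SpacerRecord",
    "AnnotationError",
    "canonical_gene_name",
    "infer_category",
    "parse_genbank",
    "parse_feature_table",
    "write_feature_table",
    "extract_feature_sequence",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "load_example_annotation",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

#: Gene-name canonicalisation map.  GenBank dialects vary wildly; this maps
#: common spellings onto the canonical labels used throughout the package.
#: Extend via the ``aliases`` argument of the parsers.
GENE_NAME_ALIASES: dict[str, str] = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad4l": "nad4L", "nad4 l": "nad4L",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox i": "cox1", "cox ii": "cox2", "cox iii": "cox3",
    "cob": "cytb", "cytochrome b": "cytb", "cyt b": "cytb",
    "atpase6": "atp6", "atpase8": "atp8", "atp 6": "atp6", "atp 8": "atp8",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "12s": "rrnS", "16s": "rrnL", "12s rrna": "rrnS", "16s rrna": "rrnL",
    "srrna": "rrnS", "lrrna": "rrnL", "rrns": "rrnS", "rrnl": "rrnL",
    "d-loop": "CR", "control region": "CR", "cr": "CR",
    "putative control region": "CR",
}

_COMPLEMENT = str.maketrans("ACGTUacgtuRYKMBVDHrykmbvdh", "TGCAAtgcaaYRMKVBHDyrmkvbhd")


class AnnotationError(ValueError):
    """Raised on malformed annotations or invalid feature geometry."""


def canonical_gene_name(raw: str, aliases: dict[str, str] | None = None) -> str:
    """Map a raw gene label onto its canonical form (e.g. ``ND5`` -> ``nad5``).

    Unrecognised labels are returned stripped but otherwise unchanged, except
    that tRNA labels are normalised to the ``trnX`` spelling.
    """
    name = raw.strip()
    table = dict(GENE_NAME_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    key = name.lower().replace("*", "").strip()
    if key in table:
        return table[key]
    if key.startswith("trn-"):
        key = "trn" + key[4:]
    if key.startswith("trna-") or key.startswith("trna "):
        key = "trn" + key[5:]
    if key.startswith("trn"):
        rest = key[3:].strip().lstrip("-")
        return "trn" + rest[:1].upper() + rest[1:]
    if key.startswith(("nad", "cox", "atp", "cytb", "rrn")):
        return key if not key.startswith("rrn") else ("rrnS" if key.endswith("s") else "rrnL")
    return name


def infer_category(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    if name == "CR":
        return "CR"
    return "PCG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated feature on a circular mitogenome."""

    name: str
    category: str
    start: int
    end: int
    strand: str | None = None  # '+', '-' or None (control region may be unset)
    wraps_origin: bool = False
    start_codon: str = ""
    stop_codon: str = ""
    anticodon: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(f"{self.name}: unknown category {self.category!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise AnnotationError(
                f"{self.name}: start {self.start} > end {self.end} without wraps_origin"
            )
        if (self.category == "tRNA") != self.name.startswith("trn"):
            raise AnnotationError(
                f"{self.name}: category tRNA iff name begins with 'trn'"
            )
        if self.anticodon and self.category != "tRNA":
            raise AnnotationError(f"{self.name}: anticodon on non-tRNA feature")

    def length_on(self, genome_length: int) -> int:
        """Feature length in bp, accounting for origin wrap."""
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class SpacerRecord:
    """Signed gap between two adjacent features; negative means overlap."""

    upstream: str
    downstream: str
    spacer: int


@dataclass
class GenomeAnnotation:
    organism: str
    length: int
    features: list[Feature]
    circular: bool = True
    accession: str = ""
    sequence: str | None = None
    #: non-fatal cross-validation messages collected while parsing
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if max(f.start, f.end) > self.length:
                raise AnnotationError(
                    f"{f.name}: coordinates exceed genome length {self.length}"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    @property
    def genes(self) -> list[Feature]:
        """All features except the control region."""
        return [f for f in self.features if f.category != "CR"]


# ---------------------------------------------------------------------------
# GenBank

_GENBANK_KEYS = {"gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def parse_genbank(text: str, aliases: dict[str, str] | None = None) -> GenomeAnnotation:
    """Parse a single-record GenBank flat file into a :class:`GenomeAnnotation`.

    ``complement(..)`` locations set strand '-'; ``join(..)`` locations that
    span the origin of a circular record set ``wraps_origin``.  ``gene``
    features that duplicate a CDS/tRNA/rRNA span are collapsed.
    """
    records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one GenBank record, got {len(records)}")
    rec = records[0]
    length = len(rec.seq) if len(rec.seq) else int(rec.annotations.get("sequence_length", 0))
    if not length:
        raise AnnotationError("cannot determine genome length from record")
    circular = rec.annotations.get("topology", "circular") == "circular"

    feats: dict[tuple, Feature] = {}
    for sf in rec.features:
        if sf.type not in _GENBANK_KEYS or sf.type == "misc_feature":
            continue
        quals = sf.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if sf.type == "D-loop" and not raw:
            raw = "CR"
        if not raw:
            raise AnnotationError(f"feature at {sf.location} has no gene/product label")
        name = canonical_gene_name(raw, aliases)
        try:
            parts = sf.location.parts
            strand = {1: "+", -1: "-", None: None}[sf.location.strand]
        except Exception as exc:  # pragma: no cover - malformed locations
            raise AnnotationError(f"malformed location for {name}: {exc}") from exc
        wraps = False
        if len(parts) == 1:
            start = int(parts[0].start) + 1
            end = int(parts[0].end)
        elif len(parts) == 2 and circular:
            # join over the origin: tail..length,1..head
            tail, head = sorted(parts, key=lambda p: p.start, reverse=True)
            if int(tail.end) != length or int(head.start) != 0:
                raise AnnotationError(f"malformed multi-part location for {name}")
            start, end, wraps = int(tail.start) + 1, int(head.end), True
        else:
            raise AnnotationError(f"malformed multi-part location for {name}")
        category = {
            "CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR",
        }.get(sf.type, infer_category(name))
        if sf.type == "gene" and (name, start, end) in {
            (f.name, f.start, f.end) for f in feats.values()
        }:
            continue
        key = (name, start, end)
        prev = feats.get(key)
        if prev is not None and sf.type == "gene":
            continue  # gene wrapper around an already-seen typed feature
        anticodon = ""
        if category == "tRNA":
            ac = quals.get("anticodon", [""])[0]
            if ac and ":" in ac:  # (pos:..,aa:..,seq:gca) style
                for part in ac.strip("()").split(","):
                    if part.startswith("seq:"):
                        anticodon = part[4:].upper().replace("U", "T")
        feats[key] = Feature(
            name=name, category=category, start=start, end=end,
            strand=strand, wraps_origin=wraps, anticodon=anticodon,
        )
    sequence = str(rec.seq) if len(rec.seq) else None
    return GenomeAnnotation(
        organism=rec.annotations.get("organism", rec.id),
        accession=rec.id if rec.id != "<unknown id>" else "",
        length=length, circular=circular, sequence=sequence,
        features=list(feats.values()),
    )


# ---------------------------------------------------------------------------
# TSV feature table

_TABLE_COLUMNS = ["gene", "from", "to", "size", "IGR", "start", "stop", "anticodon", "strand"]


def parse_feature_table(
    tsv: str,
    organism: str = "",
    length: int | None = None,
    aliases: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Parse a tab-separated mitogenome organisation table.

    Expected columns: gene, from, to, size, IGR, start, stop, anticodon,
    strand; IGR and the codon columns may be blank.  The printed ``size`` and
    ``IGR`` columns are retained for cross-validation only: recomputed values
    take precedence, and rows whose printed size disagrees with
    ``to - from + 1`` are recorded in ``annotation.warnings``.
    """
    reader = csv.DictReader(io.StringIO(tsv), delimiter="\t")
    if reader.fieldnames is None or "gene" not in reader.fieldnames:
        raise AnnotationError("feature table must have a header row with a 'gene' column")
    features: list[Feature] = []
    warnings: list[str] = []
    for row in reader:
        raw = (row.get("gene") or "").strip()
        if not raw:
            continue
        name = canonical_gene_name(raw, aliases)
        try:
            start = int(row["from"])
            end = int(row["to"])
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"row {raw!r}: bad coordinates") from exc
        strand = (row.get("strand") or "").strip().replace("−", "-") or None
        if strand not in ("+", "-", None):
            raise AnnotationError(f"row {raw!r}: bad strand {strand!r}")
        printed_size = (row.get("size") or "").strip()
        if printed_size:
            computed = end - start + 1
            if int(printed_size) != computed:
                warnings.append(
                    f"{name}: printed size {printed_size} != computed {computed}"
                )
        category = infer_category(name)
        features.append(Feature(
            name=name, category=category, start=start, end=end, strand=strand,
            start_codon=(row.get("start") or "").strip(),
            stop_codon=(row.get("stop") or "").strip(),
            anticodon=(row.get("anticodon") or "").strip() if category == "tRNA" else "",
        ))
    if not features:
        raise AnnotationError("feature table contains no features")
    genome_length = length if length is not None else max(f.end for f in features)
    ann = GenomeAnnotation(
        organism=organism, length=genome_length, features=features, circular=True,
    )
    ann.warnings.extend(warnings)
    return ann


def write_feature_table(ann: GenomeAnnotation) -> str:
    """Serialise an annotation back to the TSV dialect read by
    :func:`parse_feature_table` (gene/from/to/strand round-trip exactly)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_TABLE_COLUMNS)
    for f in ann.features:
        writer.writerow([
            f.name, f.start, f.end, f.length_on(ann.length), "",
            f.start_codon, f.stop_codon, f.anticodon, f.strand or "",
        ])
    return out.getvalue()


# ---------------------------------------------------------------------------
# Sequence access

def extract_feature_sequence(ann: GenomeAnnotation, feature: Feature) -> str:
    """Return the feature's nucleotide sequence in coding orientation.

    Plus-strand features return the slice ``start..end``; minus-strand
    features its reverse complement; origin-wrapping features concatenate
    tail and head before orienting.
    """
    if ann.sequence is None:
        raise AnnotationError("annotation carries no sequence")
    if max(feature.start, feature.end) > ann.length:
        raise AnnotationError(f"{feature.name}: coordinates exceed genome length")
    if feature.wraps_origin:
        if not ann.circular:
            raise AnnotationError(f"{feature.name}: wraps origin of a linear genome")
        raw = ann.sequence[feature.start - 1:] + ann.sequence[:feature.end]
    else:
        raw = ann.sequence[feature.start - 1:feature.end]
    return reverse_complement(raw) if feature.strand == "-" else raw


def read_fasta(text: str) -> dict[str, str]:
    recs = SeqIO.parse(io.StringIO(text), "fasta")
    return {r.id: str(r.seq) for r in recs}


def write_fasta(seqs: dict[str, str], width: int = 70) -> str:
    out = io.StringIO()
    for name, seq in seqs.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i:i + width] + "\n")
    return out.getvalue()


def load_example_annotation() -> GenomeAnnotation:
    """The bundled *Asotana magnifica* mitogenome organisation table."""
    from importlib.resources import files

    text = files("mitoskew.data").joinpath("asotana_magnifica.tsv").read_text()
    return parse_feature_table(text, organism="Asotana magnifica")
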