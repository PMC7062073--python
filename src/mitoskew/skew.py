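"""AT/GC strand-asymmetry (skew) computation and pattern classification.

AT skew = (A - T) / (A + T); GC skew = (G - C) / (G + C).  Positive AT skew
means more A than T on the strand being read, positive GC skew more G than
C.  Skews are computed at four resolutions: whole genome (majority-strand
reading), per strand class (concatenated genes in coding orientation), per
gene, and per codon position of the concatenated protein-coding genes of
each strand class.

Pattern classification uses the signs of the majority-strand pair with a
small dead-zone ``epsilon``: positive AT / negative GC is the ancestral
crustacean state, the mirrored signs the inverted state typical of most
isopods, everything else indeterminate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .annotation import AnnotationError, GenomeAnnotation, extract_feature_sequence

__all__ = [
    "BaseCounts",
    "SkewPair",
    "SkewProfile",
    "SkewPattern",
    "base_counts",
    "at_skew",
    "gc_skew",
    "skew_pair",
    "majority_strand",
    "skew_profile",
    "classify_skew_pattern",
    "StrandTieError",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.05


class StrandTieError(AnnotationError):
    """Both strands encode the same number of genes; the caller must
    designate the majority strand explicitly."""


@dataclass(frozen=True)
class BaseCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    other: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t, self.other) < 0:
            raise ValueError("base counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.other

    def __add__(self, o: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.a + o.a, self.c + o.c, self.g + o.g,
                          self.t + o.t, self.other + o.other)


@dataclass(frozen=True)
class SkewPair:
    """AT and GC skew of one sequence; ``None`` marks an undefined value
    (zero denominator).  Ambiguity codes never enter the denominators."""

    at_skew: float | None
    gc_skew: float | None


def base_counts(seq: str) -> BaseCounts:
    """Case-insensitive tallies; every non-ACGT symbol counts as 'other'."""
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return BaseCounts(a=a, c=c, g=g, t=t, other=len(s) - a - c - g - t)


def at_skew(counts: BaseCounts) -> float | None:
    denom = counts.a + counts.t
    return (counts.a - counts.t) / denom if denom else None


def gc_skew(counts: BaseCounts) -> float | None:
    denom = counts.g + counts.c
    return (counts.g - counts.c) / denom if denom else None


def skew_pair(seq: str) -> SkewPair:
    counts = base_counts(seq)
    return SkewPair(at_skew(counts), gc_skew(counts))


def majority_strand(ann: GenomeAnnotation) -> str:
    """The strand encoding strictly more gene features (CR excluded).

    A tie raises :class:`StrandTieError` rather than silently picking a
    side — a wrong majority call flips every downstream skew sign.
    """
    plus = sum(1 for f in ann.genes if f.strand == "+")
    minus = sum(1 for f in ann.genes if f.strand == "-")
    if plus + minus == 0:
        raise AnnotationError("no stranded gene features")
    if plus == minus:
        raise StrandTieError(
            f"strand tie ({plus} vs {minus}); designate the majority strand"
        )
    return "+" if plus > minus else "-"


@dataclass
class SkewProfile:
    whole_genome: SkewPair
    majority: str
    #: 'majority' / 'minority' -> skews of the concatenated genes of that
    #: strand class, each gene read in its own coding orientation
    per_strand_class: dict[str, SkewPair]
    #: gene label -> skews in coding orientation
    per_gene: dict[str, SkewPair]
    #: (strand class, codon position 1/2/3) -> skews over concatenated PCGs,
    #: complete codons only
    per_codon_position: dict[tuple[str, int], SkewPair]
    warnings: list[str] = field(default_factory=list)


def skew_profile(ann: GenomeAnnotation, majority: str | None = None) -> SkewProfile:
    """Full skew profile of one annotated mitogenome with sequence.

    The whole-genome pair is computed on the majority-strand reading of the
    complete sequence.  Per-gene pairs use each gene's coding orientation;
    strand classes concatenate those coding-orientation sequences, so the
    minority-class values are reported in minority-strand reading.  Codon
    positions partition the concatenated PCGs of each class; genes whose
    length is not a multiple of 3 (truncated stop codons) drop the trailing
    partial codon with a warning.
    """
    if ann.sequence is None:
        raise AnnotationError("skew profile requires the genome sequence")
    maj = majority if majority is not None else majority_strand(ann)
    warnings: list[str] = []

    genome = ann.sequence
    if maj == "-":
        from .annotation import reverse_complement
        genome = reverse_complement(genome)
    whole = skew_pair(genome)

    per_gene: dict[str, SkewPair] = {}
    class_seq = {"majority": [], "minority": []}
    codon_seq = {("majority", 1): [], ("majority", 2): [], ("majority", 3): [],
                 ("minority", 1): [], ("minority", 2): [], ("minority", 3): []}
    for f in ann.genes:
        seq = extract_feature_sequence(ann, f)
        per_gene[f.name] = skew_pair(seq)
        cls = "majority" if (f.strand or "+") == maj else "minority"
        class_seq[cls].append(seq)
        if f.category == "PCG":
            if len(seq) % 3:
                warnings.append(
                    f"{f.name}: length {len(seq)} not divisible by 3; "
                    f"dropped trailing partial codon"
                )
                seq = seq[: len(seq) - len(seq) % 3]
            for pos in (1, 2, 3):
                codon_seq[(cls, pos)].append(seq[pos - 1::3])

    per_class = {cls: skew_pair("".join(parts)) for cls, parts in class_seq.items()}
    per_codon = {key: skew_pair("".join(parts)) for key, parts in codon_seq.items()}
    return SkewProfile(
        whole_genome=whole, majority=maj, per_strand_class=per_class,
        per_gene=per_gene, per_codon_position=per_codon, warnings=warnings,
    )


class SkewPattern(enum.Enum):
    CRUSTACEAN_TYPE = "CRUSTACEAN_TYPE"   # AT skew > eps, GC skew < -eps
    INVERTED_TYPE = "INVERTED_TYPE"       # AT skew < -eps, GC skew > eps
    INDETERMINATE = "INDETERMINATE"


def classify_skew_pattern(pair: SkewPair, epsilon: float = DEFAULT_EPSILON) -> SkewPattern:
    """Classify a majority-strand skew pair by sign with a dead-zone.

    Undefined skews are INDETERMINATE.  The dead-zone prevents noise-driven
    flips on short sequences; set ``epsilon=0`` for pure sign classification.
    """
    if pair.at_skew is None or pair.gc_skew is None:
        return SkewPattern.INDETERMINATE
    if pair.at_skew > epsilon and pair.gc_skew < -epsilon:
        return SkewPattern.CRUSTACEAN_TYPE
    if pair.at_skew < -epsilon and pair.gc_skew > epsilon:
        return SkewPattern.INVERTED_TYPE
    return SkewPattern.INDETERMINATE
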