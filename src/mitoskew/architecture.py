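"""Mitogenome architecture statistics and circular gene-order comparison.

Spacer/overlap accounting treats the genome as circular: every adjacent
feature pair, including the wrap from the last feature back to the first,
yields exactly one signed :class:`~mitoskew.annotation.SpacerRecord`
(negative = overlap).  Gene orders are circular signed permutations compared
up to rotation (reflections are *not* identified: strand flips carry
biological meaning here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import AnnotationError, GenomeAnnotation, SpacerRecord

__all__ = [
    "NcrRegion",
    "GeneOrder",
    "SignedLabel",
    "spacers",
    "ncr_catalog",
    "gene_order",
    "adjacency_set",
    "breakpoint_distance",
    "is_unique_order",
    "max_overlap",
    "architecture_summary",
]


@dataclass
class NcrRegion:
    start: int
    end: int
    kind: str  # 'intergenic' or 'control_region'
    neighbors: tuple[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: A signed gene label: (name, sign) with sign +1 / -1 for strand.
SignedLabel = tuple[str, int]


def spacers(ann: GenomeAnnotation, warn: list[str] | None = None) -> list[SpacerRecord]:
    """One record per adjacent feature pair on the circular coordinate system.

    ``spacer = next.start - prev.end - 1``; for the origin-wrapping pair the
    next start is shifted by the genome length.  Overlap counting is purely
    positional (strand-blind).  Triples of features sharing a base are
    reported into ``warn`` but records are still emitted pairwise.
    """
    feats = ann.features
    if len(feats) < 2:
        raise AnnotationError("need at least two features to compute spacers")
    records = []
    for prev, nxt in zip(feats, feats[1:]):
        records.append(SpacerRecord(prev.name, nxt.name, nxt.start - prev.end - 1))
    if ann.circular:
        first, last = feats[0], feats[-1]
        records.append(SpacerRecord(
            last.name, first.name, first.start + ann.length - last.end - 1,
        ))
    if warn is not None:
        for a, b, c in zip(feats, feats[1:], feats[2:]):
            if c.start <= a.end:  # a base shared by three consecutive features
                warn.append(f"triple overlap: {a.name}/{b.name}/{c.name}")
    return records


def ncr_catalog(ann: GenomeAnnotation, min_len: int = 1) -> list[NcrRegion]:
    """Non-coding regions: every positive inter-feature spacer of at least
    ``min_len`` bp, plus the annotated control region, sorted by start."""
    regions = []
    for rec in spacers(ann):
        if rec.spacer >= max(min_len, 1):
            up = ann.get(rec.upstream)
            start = up.end + 1
            if start > ann.length:
                start -= ann.length
            regions.append(NcrRegion(
                start=start, end=start + rec.spacer - 1, kind="intergenic",
                neighbors=(rec.upstream, rec.downstream),
            ))
    for f in ann.features:
        if f.category == "CR":
            idx = ann.features.index(f)
            prev = ann.features[idx - 1]
            nxt = ann.features[(idx + 1) % len(ann.features)]
            regions.append(NcrRegion(
                start=f.start, end=f.end, kind="control_region",
                neighbors=(prev.name, nxt.name),
            ))
    return sorted(regions, key=lambda r: r.start)


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed permutation of gene labels (sign = strand)."""

    labels: tuple[SignedLabel, ...]
    genome_id: str = ""

    def __post_init__(self) -> None:
        names = [n for n, _ in self.labels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate gene labels: {', '.join(dupes)}")

    def canonical(self) -> tuple[SignedLabel, ...]:
        """Rotation putting the lexicographically smallest label first."""
        names = [n for n, _ in self.labels]
        k = names.index(min(names))
        return self.labels[k:] + self.labels[:k]

    def __eq__(self, other: object) -> bool:  # rotation-invariant
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __str__(self) -> str:
        return " ".join(("+" if s > 0 else "-") + n for n, s in self.canonical())


def gene_order(ann: GenomeAnnotation, include_cr: bool = False) -> GeneOrder:
    """Extract the circular signed gene order, in coordinate order.

    The control region is excluded by default (gene-arrangement comparisons
    ignore it) but participates when ``include_cr`` is set; an unset strand
    counts as '+'.
    """
    labels = []
    for f in ann.features:
        if f.category == "CR" and not include_cr:
            continue
        labels.append((f.name, -1 if f.strand == "-" else 1))
    if not labels:
        raise AnnotationError("no features to order")
    return GeneOrder(tuple(labels), genome_id=ann.organism or ann.accession)


def _norm_adjacency(a: SignedLabel, b: SignedLabel) -> tuple[SignedLabel, SignedLabel]:
    """Normalise (a,b) so that (a,b) and (-b,-a) collapse to one key."""
    mirrored = ((b[0], -b[1]), (a[0], -a[1]))
    return min((a, b), mirrored)


def adjacency_set(order: GeneOrder) -> frozenset:
    """The n circular signed adjacencies of an n-label order, normalised so
    that reading an adjacency from the other strand gives the same key."""
    labs = order.labels
    return frozenset(
        _norm_adjacency(labs[i], labs[(i + 1) % len(labs)]) for i in range(len(labs))
    )


def breakpoint_distance(
    o1: GeneOrder, o2: GeneOrder, warn: list[str] | None = None
) -> int:
    """Number of adjacencies of ``o1`` absent from ``o2``, after restricting
    both orders to their shared (unsigned) label set.

    Labels present in only one order are dropped with a warning — compact
    mitogenomes frequently lack individual tRNAs.  Zero iff the restricted
    orders are equal up to rotation.
    """
    names1 = {n for n, _ in o1.labels}
    names2 = {n for n, _ in o2.labels}
    shared = names1 & names2
    if not shared:
        raise AnnotationError("orders share no gene labels")
    dropped = (names1 | names2) - shared
    if dropped and warn is not None:
        warn.append(f"dropped {len(dropped)} unshared labels: {', '.join(sorted(dropped))}")
    r1 = GeneOrder(tuple(l for l in o1.labels if l[0] in shared), o1.genome_id)
    r2 = GeneOrder(tuple(l for l in o2.labels if l[0] in shared), o2.genome_id)
    return len(adjacency_set(r1) - adjacency_set(r2))


@dataclass
class UniquenessReport:
    unique: bool
    min_distance: int
    nearest: str
    distances: dict[str, int] = field(default_factory=dict)


def is_unique_order(order: GeneOrder, others) -> UniquenessReport:
    """True iff the order differs (breakpoint distance > 0) from every
    comparator; the report carries the nearest comparator."""
    others = list(others)
    if not others:
        raise AnnotationError("need at least one comparator order")
    distances = {o.genome_id or f"order{i}": breakpoint_distance(order, o)
                 for i, o in enumerate(others)}
    nearest = min(distances, key=lambda k: (distances[k], k))
    return UniquenessReport(
        unique=all(d > 0 for d in distances.values()),
        min_distance=distances[nearest], nearest=nearest, distances=distances,
    )


def max_overlap(ann: GenomeAnnotation, categories: tuple[str, str] | None = None) -> int:
    """Largest overlap (bp) between adjacent features, optionally restricted
    to pairs whose categories both match ``categories`` (e.g. PCG-PCG).

    Returns 0 when no qualifying overlap exists.
    """
    best = 0
    cat = {f.name: f.category for f in ann.features}
    for rec in spacers(ann):
        if rec.spacer >= 0:
            continue
        if categories is not None:
            if not (cat[rec.upstream] in categories and cat[rec.downstream] in categories):
                continue
        best = max(best, -rec.spacer)
    return best


def architecture_summary(ann: GenomeAnnotation) -> dict:
    """Headline counts for one genome (feature census, overlaps, NCRs)."""
    recs = spacers(ann)
    ncrs = ncr_catalog(ann)
    return {
        "organism": ann.organism,
        "length": ann.length,
        "n_features": len(ann.features),
        "n_pcg": len(ann.by_category("PCG")),
        "n_trna": len(ann.by_category("tRNA")),
        "n_rrna": len(ann.by_category("rRNA")),
        "n_minus_strand_genes": sum(1 for f in ann.genes if f.strand == "-"),
        "n_overlaps": sum(1 for r in recs if r.spacer < 0),
        "n_ncr": len(ncrs),
        "n_ncr_gt10": sum(1 for r in ncrs if r.length > 10),
        "max_overlap": max_overlap(ann),
        "max_overlap_pcg": max_overlap(ann, categories=("PCG", "PCG")),
    }
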