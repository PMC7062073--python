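"""Scan non-coding regions for residual tRNA anticodon hairpins.

Degenerate tRNA genes can survive in intergenic spacers as little more than
their anticodon arm: a paired stem enclosing a 7-nt loop with the anticodon
at loop positions 3-5.  This module searches candidate windows (NCRs plus
short flanks into the neighbouring genes) on both strands for exactly that
minimal geometry.  Stems allow GU wobble pairs; the score of a hit is the
stem length, keeping every call exactly reproducible by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import (
    AnnotationError,
    GenomeAnnotation,
    reverse_complement,
)
from .architecture import ncr_catalog

__all__ = [
    "TrnaFragmentHit",
    "ScanWindow",
    "STANDARD_MT_ANTICODONS",
    "candidate_windows",
    "scan_anticodon_hairpins",
    "scan_genome",
]

#: DNA-alphabet anticodons of the 22 standard metazoan mitochondrial tRNAs.
STANDARD_MT_ANTICODONS: dict[str, str] = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC",
    "trnC": "GCA", "trnQ": "TTG", "trnE": "TTC", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnL1": "TAG", "trnL2": "TAA",
    "trnK": "TTT", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnW": "TCA",
    "trnY": "GTA", "trnV": "TAC",
}

LOOP_LEN = 7
#: 0-based offset of the anticodon within the 7-nt loop (loop positions 3-5)
ANTICODON_OFFSET = 2

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class ScanWindow:
    """A candidate region: an NCR expanded by a flank into its neighbours."""

    region_id: str
    start: int  # 1-based, genome coordinates (may wrap on circular genomes)
    end: int
    sequence: str


@dataclass(frozen=True)
class TrnaFragmentHit:
    region_id: str
    strand: str  # '+' or '-'
    offset: int  # 1-based anticodon start within the scanned-strand reading
    anticodon: str
    trna: str
    stem_len: int

    @property
    def score(self) -> int:
        return self.stem_len


def candidate_windows(
    ann: GenomeAnnotation, min_ncr: int = 10, flank: int = 20
) -> list[ScanWindow]:
    """NCRs longer than ``min_ncr`` bp, each expanded by ``flank`` bp into
    both neighbouring genes (wrapping on circular genomes, clipped on
    linear ones)."""
    if ann.sequence is None:
        raise AnnotationError("candidate windows require the genome sequence")
    n = ann.length
    windows = []
    for region in ncr_catalog(ann):
        if region.length <= min_ncr:
            continue
        start = region.start - flank
        end = region.end + flank
        if ann.circular:
            seq = _circular_slice(ann.sequence, start, end)
        else:
            start, end = max(1, start), min(n, end)
            seq = ann.sequence[start - 1:end]
        rid = f"{region.neighbors[0]}-{region.neighbors[1]}"
        if region.kind == "control_region":
            rid = f"CR({rid})"
        windows.append(ScanWindow(region_id=rid, start=start, end=end, sequence=seq))
    return windows


def _circular_slice(sequence: str, start: int, end: int) -> str:
    n = len(sequence)
    return "".join(sequence[(i - 1) % n] for i in range(start, end + 1))


def _paired(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


def _stem_length(seq: str, loop_start: int) -> int:
    """Contiguous Watson-Crick/GU pairs closing a loop at [loop_start,
    loop_start+LOOP_LEN) of ``seq`` (0-based), innermost pair first."""
    k = 0
    while True:
        left = loop_start - 1 - k
        right = loop_start + LOOP_LEN + k
        if left < 0 or right >= len(seq):
            break
        if not _paired(seq[left], seq[right]):
            break
        k += 1
    return k


def scan_anticodon_hairpins(
    seq: str,
    anticodons: dict[str, str] | None = None,
    min_stem: int = 3,
    region_id: str = "",
) -> list[TrnaFragmentHit]:
    """Find anticodon hairpins on both strands of ``seq``.

    A hit at anticodon offset ``o`` (1-based) requires a 7-nt loop with a
    known anticodon at loop positions 3-5, closed by at least ``min_stem``
    contiguous canonical or GU pairs.  Minus-strand hits report offsets in
    the reverse-complement reading, so hits on ``revcomp(seq)`` are exactly
    the strand-swapped hits on ``seq``.  Hits are sorted by score (desc),
    then strand, then offset.
    """
    table = STANDARD_MT_ANTICODONS if anticodons is None else anticodons
    if not table:
        raise ValueError("anticodon table is empty")
    by_anticodon: dict[str, list[str]] = {}
    for trna, ac in table.items():
        by_anticodon.setdefault(ac.upper().replace("U", "T"), []).append(trna)

    hits: list[TrnaFragmentHit] = []
    for strand, s in (("+", seq.upper()), ("-", reverse_complement(seq).upper())):
        for loop_start in range(0, len(s) - LOOP_LEN + 1):
            ac = s[loop_start + ANTICODON_OFFSET:loop_start + ANTICODON_OFFSET + 3]
            if ac not in by_anticodon:
                continue
            stem = _stem_length(s, loop_start)
            if stem < min_stem:
                continue
            offset = loop_start + ANTICODON_OFFSET + 1
            for trna in sorted(by_anticodon[ac]):
                hits.append(TrnaFragmentHit(
                    region_id=region_id, strand=strand, offset=offset,
                    anticodon=ac, trna=trna, stem_len=stem,
                ))
    hits.sort(key=lambda h: (-h.stem_len, h.strand, h.offset, h.trna))
    return hits


def scan_genome(
    ann: GenomeAnnotation,
    anticodons: dict[str, str] | None = None,
    min_ncr: int = 10,
    flank: int = 20,
    min_stem: int = 3,
) -> list[TrnaFragmentHit]:
    """Run the hairpin scan over every candidate NCR window of a genome."""
    hits: list[TrnaFragmentHit] = []
    for window in candidate_windows(ann, min_ncr=min_ncr, flank=flank):
        hits.extend(scan_anticodon_hairpins(
            window.sequence, anticodons=anticodons, min_stem=min_stem,
            region_id=window.region_id,
        ))
    return hits
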