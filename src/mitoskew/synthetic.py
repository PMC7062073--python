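"""Synthetic mitogenomes and alignments with controlled compositional bias.

Two generators:

* :func:`simulate_mitogenome` builds a circular annotated genome whose
  architecture (gene labels, lengths, strands, spacers/overlaps, control
  region) follows a template exactly and whose per-strand-class / per-codon-
  position base composition follows configurable skew targets.

* :func:`simulate_skewed_alignment` evolves sequences down a known tree
  under a composition-biased replacement model: along a branch of expected
  length *b*, each site is replaced with probability ``1 - exp(-b)`` by a
  draw from the base-frequency vector of the child lineage's composition
  group.  Designated groups of taxa thereby converge on homoplastic
  compositions irrespective of their true tree distance — the regime in
  which compositional long-branch attraction is testable.

Both generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .annotation import Feature, GenomeAnnotation, infer_category
from .skew import SkewPair

__all__ = [
    "GeneSpec",
    "GenomeSimConfig",
    "AlignmentSimConfig",
    "Alignment",
    "ConfigError",
    "composition_from_skews",
    "simulate_mitogenome",
    "simulate_skewed_alignment",
    "template_from_annotation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GeneSpec:
    name: str
    length: int
    strand: str  # '+' or '-'
    category: str = ""

    def resolved_category(self) -> str:
        return self.category or infer_category(self.name)


@dataclass
class GenomeSimConfig:
    """Architecture template plus compositional targets for one genome.

    ``spacers[i]`` is the signed gap preceding gene ``i`` (negative =
    overlap with the previous gene); ``spacers[0]`` offsets the first gene
    from position 1.  A control region of ``cr_length`` bp (if non-zero) is
    appended after the last gene, separated by ``cr_spacer``.
    """

    genes: list[GeneSpec]
    spacers: list[int]
    seed: int
    cr_length: int = 0
    cr_spacer: int = 0
    trailing_gap: int = 0
    at_fraction: float = 0.65
    strand_targets: dict[str, SkewPair] = field(default_factory=lambda: {
        "majority": SkewPair(0.1, -0.4),
        "minority": SkewPair(-0.3, 0.6),
    })
    #: optional (strand class, codon position) -> SkewPair overrides for PCGs
    codon_targets: dict[tuple[str, int], SkewPair] = field(default_factory=dict)
    majority: str | None = None  # override when the template is strand-tied
    organism: str = "simulated"

    def validate(self) -> None:
        if len(self.spacers) != len(self.genes):
            raise ConfigError("need one spacer entry per gene")
        if not self.genes:
            raise ConfigError("empty gene template")
        for g in self.genes:
            if g.length <= 0:
                raise ConfigError(f"{g.name}: non-positive length")
            if (g.resolved_category() == "PCG" and g.length % 3
                    and self.codon_targets):
                # real annotations carry truncated stop codons; only reject
                # partial codons when codon-position targets are in play
                raise ConfigError(
                    f"{g.name}: PCG length must be divisible by 3 "
                    f"when codon-position targets are set"
                )
            if g.strand not in ("+", "-"):
                raise ConfigError(f"{g.name}: strand must be + or -")
        if not 0.0 < self.at_fraction < 1.0:
            raise ConfigError("at_fraction must lie in (0, 1)")
        targets = list(self.strand_targets.values()) + list(self.codon_targets.values())
        for pair in targets:
            for v in (pair.at_skew, pair.gc_skew):
                if v is None or not -1.0 < v < 1.0:
                    raise ConfigError(f"skew target {v} outside (-1, 1)")


def composition_from_skews(
    pair: SkewPair, at_fraction: float
) -> np.ndarray:
    """Base frequencies (A, C, G, T) realising the given skews at the given
    AT content: p_A = f(1+sAT)/2, p_T = f(1-sAT)/2 and analogously for G/C."""
    s_at = pair.at_skew if pair.at_skew is not None else 0.0
    s_gc = pair.gc_skew if pair.gc_skew is not None else 0.0
    f = at_fraction
    p = np.array([
        f * (1 + s_at) / 2,
        (1 - f) * (1 - s_gc) / 2,
        (1 - f) * (1 + s_gc) / 2,
        f * (1 - s_at) / 2,
    ])
    if np.any(p <= 0) or np.any(p >= 1):
        raise ConfigError(f"infeasible composition for skews {pair} at AT={at_fraction}")
    return p


def _complement_freqs(p: np.ndarray) -> np.ndarray:
    # A<->T, C<->G
    return p[[3, 2, 1, 0]]


def _template_majority(cfg: GenomeSimConfig) -> str:
    if cfg.majority is not None:
        return cfg.majority
    plus = sum(1 for g in cfg.genes if g.strand == "+")
    minus = len(cfg.genes) - plus
    if plus == minus:
        raise ConfigError("template is strand-tied; set cfg.majority explicitly")
    return "+" if plus > minus else "-"


def simulate_mitogenome(cfg: GenomeSimConfig) -> GenomeAnnotation:
    """Generate a circular annotated genome matching the template exactly.

    Each gene's bases are drawn i.i.d. from the composition implied by its
    strand class (and, for PCGs, by per-codon-position targets when
    provided), in coding orientation, then placed on the plus strand.
    Where features overlap, the later feature's draw wins; intergenic and
    CR bases come from the majority-class background composition.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    maj = _template_majority(cfg)

    # lay out coordinates
    feats: list[Feature] = []
    prev_end = 0
    for g, gap in zip(cfg.genes, cfg.spacers):
        start = prev_end + gap + 1
        if start < 1:
            raise ConfigError(f"{g.name}: layout places start before position 1")
        end = start + g.length - 1
        feats.append(Feature(
            name=g.name, category=g.resolved_category(),
            start=start, end=end, strand=g.strand,
        ))
        prev_end = end
    if cfg.cr_length:
        start = prev_end + cfg.cr_spacer + 1
        feats.append(Feature(
            name="CR", category="CR", start=start,
            end=start + cfg.cr_length - 1, strand=None,
        ))
        prev_end = feats[-1].end
    genome_length = prev_end + cfg.trailing_gap

    background = composition_from_skews(cfg.strand_targets["majority"], cfg.at_fraction)
    if maj == "-":
        background = _complement_freqs(background)
    seq = rng.choice(4, size=genome_length, p=background)

    for f in feats:
        if f.category == "CR":
            continue
        cls = "majority" if f.strand == maj else "minority"
        n = f.end - f.start + 1
        if f.category == "PCG" and any(k[0] == cls for k in cfg.codon_targets):
            coding = np.empty(n, dtype=np.int64)
            for pos in (1, 2, 3):
                pair = cfg.codon_targets.get((cls, pos), cfg.strand_targets[cls])
                p = composition_from_skews(pair, cfg.at_fraction)
                m = len(coding[pos - 1::3])
                coding[pos - 1::3] = rng.choice(4, size=m, p=p)
        else:
            p = composition_from_skews(cfg.strand_targets[cls], cfg.at_fraction)
            coding = rng.choice(4, size=n, p=p)
        if f.strand == "-":
            coding = 3 - coding[::-1]  # reverse complement in ACGT integer coding
        seq[f.start - 1:f.end] = coding

    return GenomeAnnotation(
        organism=cfg.organism, length=genome_length, circular=True,
        sequence="".join(_BASES[seq]), features=feats,
    )


def template_from_annotation(
    ann: GenomeAnnotation, seed: int = 0, **overrides
) -> GenomeSimConfig:
    """Copy an existing annotation's architecture (labels, lengths, strands,
    spacers, CR) into a simulation config.  The control region, if present,
    must be the final feature."""
    from .architecture import spacers as spacer_records

    feats = ann.features
    cr = [f for f in feats if f.category == "CR"]
    if cr and feats[-1].category != "CR":
        raise ConfigError("template extraction requires the CR to be the final feature")
    genes = [
        GeneSpec(name=f.name, length=f.length_on(ann.length),
                 strand=f.strand or "+", category=f.category)
        for f in feats if f.category != "CR"
    ]
    recs = spacer_records(ann)
    gaps = [feats[0].start - 1]
    gaps += [rec.spacer for rec in recs[:len(genes) - 1]]
    cr_spacer = recs[len(genes) - 1].spacer if cr else 0
    trailing = ann.length - feats[-1].end
    return GenomeSimConfig(
        genes=genes, spacers=gaps, seed=seed,
        cr_length=cr[0].length_on(ann.length) if cr else 0,
        cr_spacer=cr_spacer, trailing_gap=trailing,
        organism=f"sim({ann.organism})" if ann.organism else "simulated",
        **overrides,
    )


# ---------------------------------------------------------------------------
# Multi-taxon alignments with lineage-specific compositional shifts


@dataclass
class AlignmentSimConfig:
    """Config for the composition-biased replacement simulator.

    ``tree`` is rooted Newick with branch lengths in expected substitutions
    per site.  Every leaf taxon must appear in ``groups``; substitutions on
    a terminal branch draw replacement bases from the taxon's group
    composition, while internal branches (and the root sequence) use
    ``root_group``.  Compositions are (A, C, G, T) frequency vectors.
    """

    tree: str
    groups: dict[str, str]
    group_freqs: dict[str, tuple[float, float, float, float]]
    root_group: str
    length: int
    seed: int

    def validate(self) -> None:
        if self.length <= 0:
            raise ConfigError("alignment length must be positive")
        for group, freqs in self.group_freqs.items():
            arr = np.asarray(freqs, dtype=float)
            if arr.shape != (4,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-6:
                raise ConfigError(f"group {group}: frequencies must be 4 values summing to 1")
        missing = set(self.groups.values()) - set(self.group_freqs)
        if self.root_group not in self.group_freqs:
            missing.add(self.root_group)
        if missing:
            raise ConfigError(f"groups without frequency vectors: {sorted(missing)}")


@dataclass
class Alignment:
    sequences: dict[str, str]  # taxon -> aligned sequence
    tree: str = ""
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def to_fasta(self) -> str:
        from .annotation import write_fasta

        return write_fasta(self.sequences)


def simulate_skewed_alignment(cfg: AlignmentSimConfig) -> Alignment:
    """Simulate leaf sequences under the composition-biased replacement
    model; deterministic given ``cfg.seed``.  Raises on any mismatch between
    the tree's leaf set and the configured taxa."""
    cfg.validate()
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaves != set(cfg.groups):
        raise ConfigError(
            f"tree/taxon mismatch: tree has {sorted(leaves)}, "
            f"config has {sorted(cfg.groups)}"
        )
    rng = np.random.default_rng(cfg.seed)
    freqs = {g: np.asarray(f, dtype=float) for g, f in cfg.group_freqs.items()}
    freqs = {g: f / f.sum() for g, f in freqs.items()}

    root = tree.seed_node
    node_seq = {root: rng.choice(4, size=cfg.length, p=freqs[cfg.root_group])}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = node_seq[node.parent_node]
        b = node.edge.length or 0.0
        p_sub = 1.0 - np.exp(-b)
        seq = parent_seq.copy()
        mask = rng.random(cfg.length) < p_sub
        group = cfg.groups[node.taxon.label] if node.is_leaf() else cfg.root_group
        n_sub = int(mask.sum())
        if n_sub:
            seq[mask] = rng.choice(4, size=n_sub, p=freqs[group])
        node_seq[node] = seq
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[seq])
    return Alignment(sequences=out, tree=cfg.tree, groups=dict(cfg.groups))
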