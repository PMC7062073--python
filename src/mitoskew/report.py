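"""Report assembly: per-genome architecture/skew bundles and cross-genome
comparisons, serialised as diff-able TSV + JSON only.

Every value in a report is produced by calling the underlying module
operation; nothing is computed here that cannot be recomputed directly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import architecture, ncrscan, skew
from .annotation import GenomeAnnotation, write_feature_table

__all__ = ["RunConfig", "genome_report", "cross_genome_report", "write_report_bundle"]


@dataclass
class RunConfig:
    """Knobs shared by the reporting pipeline, with package-wide defaults."""

    epsilon: float = skew.DEFAULT_EPSILON  # skew-pattern dead-zone
    min_ncr: int = 10                      # NCR size gate for hairpin windows
    flank: int = 20                        # flank into neighbouring genes
    min_stem: int = 3                      # minimum hairpin stem pairs
    seed: int = 0
    formats: tuple[str, ...] = ("tsv", "json")

    def validate(self) -> None:
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.min_ncr < 0 or self.flank < 0 or self.min_stem < 1:
            raise ValueError("min_ncr/flank must be >= 0 and min_stem >= 1")


def _pair(p: skew.SkewPair) -> dict:
    return {"at_skew": p.at_skew, "gc_skew": p.gc_skew}


def genome_report(ann: GenomeAnnotation, cfg: RunConfig | None = None) -> dict:
    """Full single-genome bundle.  Without a sequence the report downgrades
    to architecture-only and records a warning."""
    cfg = cfg or RunConfig()
    cfg.validate()
    warnings = list(ann.warnings)
    report = {
        "organism": ann.organism,
        "summary": architecture.architecture_summary(ann),
        "feature_table": write_feature_table(ann),
        "spacers": [
            {"upstream": r.upstream, "downstream": r.downstream, "spacer": r.spacer}
            for r in architecture.spacers(ann)
        ],
        "ncr_catalog": [
            {"start": r.start, "end": r.end, "length": r.length, "kind": r.kind,
             "neighbors": list(r.neighbors)}
            for r in architecture.ncr_catalog(ann)
        ],
        "gene_order": str(architecture.gene_order(ann)),
    }
    if ann.sequence is None:
        warnings.append("no sequence: skew profile and NCR scan skipped")
        report["skew"] = None
        report["ncr_hits"] = None
    else:
        profile = skew.skew_profile(ann)
        warnings.extend(profile.warnings)
        report["skew"] = {
            "majority_strand": profile.majority,
            "whole_genome": _pair(profile.whole_genome),
            "per_strand_class": {k: _pair(v) for k, v in profile.per_strand_class.items()},
            "per_gene": {k: _pair(v) for k, v in profile.per_gene.items()},
            "per_codon_position": {
                f"{cls}/{pos}": _pair(v)
                for (cls, pos), v in profile.per_codon_position.items()
            },
            "pattern": skew.classify_skew_pattern(
                profile.whole_genome, epsilon=cfg.epsilon).value,
        }
        report["ncr_hits"] = [
            {"region": h.region_id, "strand": h.strand, "offset": h.offset,
             "anticodon": h.anticodon, "trna": h.trna, "stem_len": h.stem_len}
            for h in ncrscan.scan_genome(
                ann, min_ncr=cfg.min_ncr, flank=cfg.flank, min_stem=cfg.min_stem)
        ]
    report["warnings"] = warnings
    return report


def cross_genome_report(anns: list[GenomeAnnotation], cfg: RunConfig | None = None) -> dict:
    """Pairwise breakpoint distances and per-genome uniqueness flags."""
    cfg = cfg or RunConfig()
    orders = [architecture.gene_order(a) for a in anns]
    ids = [o.genome_id or f"genome{i}" for i, o in enumerate(orders)]
    matrix = [
        [architecture.breakpoint_distance(a, b) for b in orders] for a in orders
    ]
    uniqueness = {}
    if len(orders) > 1:
        for i, o in enumerate(orders):
            rep = architecture.is_unique_order(o, orders[:i] + orders[i + 1:])
            uniqueness[ids[i]] = {
                "unique": rep.unique, "min_distance": rep.min_distance,
                "nearest": rep.nearest,
            }
    return {"genomes": ids, "breakpoint_matrix": matrix, "uniqueness": uniqueness}


def _spacers_tsv(report: dict) -> str:
    out = io.StringIO()
    out.write("upstream\tdownstream\tspacer\n")
    for r in report["spacers"]:
        out.write(f"{r['upstream']}\t{r['downstream']}\t{r['spacer']}\n")
    return out.getvalue()


def _ncr_tsv(report: dict) -> str:
    out = io.StringIO()
    out.write("start\tend\tlength\tkind\tupstream\tdownstream\n")
    for r in report["ncr_catalog"]:
        out.write(f"{r['start']}\t{r['end']}\t{r['length']}\t{r['kind']}\t"
                  f"{r['neighbors'][0]}\t{r['neighbors'][1]}\n")
    return out.getvalue()


def _skew_tsv(report: dict) -> str:
    out = io.StringIO()
    out.write("scope\tname\tat_skew\tgc_skew\n")
    sk = report["skew"]
    if sk is None:
        return out.getvalue()

    def fmt(v):
        return "NA" if v is None else f"{v:.6f}"

    def row(scope, name, p):
        out.write(f"{scope}\t{name}\t{fmt(p['at_skew'])}\t{fmt(p['gc_skew'])}\n")

    row("whole_genome", report["organism"] or "genome", sk["whole_genome"])
    for k, p in sk["per_strand_class"].items():
        row("strand_class", k, p)
    for k, p in sk["per_gene"].items():
        row("gene", k, p)
    for k, p in sk["per_codon_position"].items():
        row("codon_position", k, p)
    return out.getvalue()


def write_report_bundle(
    anns: list[GenomeAnnotation], outdir: str | Path, cfg: RunConfig | None = None
) -> list[Path]:
    """Write one report bundle per genome plus the cross-genome summary.
    Returns the written paths; output is byte-stable for fixed inputs."""
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, ann in enumerate(anns):
        stem = (ann.organism or f"genome{i}").replace(" ", "_").replace("/", "_")
        rep = genome_report(ann, cfg)
        if "json" in cfg.formats:
            path = outdir / f"{stem}.report.json"
            path.write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
            written.append(path)
        if "tsv" in cfg.formats:
            for suffix, text in (
                (".spacers.tsv", _spacers_tsv(rep)),
                (".ncr.tsv", _ncr_tsv(rep)),
                (".skew.tsv", _skew_tsv(rep)),
            ):
                path = outdir / (stem + suffix)
                path.write_text(text)
                written.append(path)
    cross = cross_genome_report(anns, cfg)
    path = outdir / "cross_genomes.json"
    path.write_text(json.dumps(cross, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
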