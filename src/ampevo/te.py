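"""Transposable-element annotation cleanup and gene-structure statistics.

RepeatMasker-style TE annotations frequently contain fragmented or doubly
masked calls: the same insertion reported twice with slightly shifted
coordinates, or nested fragments of one element.  Counting those naively
inflates per-gene TE loads.  The resolution rule implemented here merges
same-strand calls that lie within 10 bp of each other and reciprocally cover
at least 80% of the longer element; unresolvable overlaps keep the copy with
the lowest divergence to its family consensus (the least-decayed, hence
best-supported, call).  Simple repeats and low-complexity annotations are
discarded outright.

Downstream, TEs are intersected with AMP gene models to summarise intronic
TE load per gene (exon-overlapping TEs are tagged and excluded), and genes
are summarised per AMP family by exon-count spectrum and length range.
Clusters of neighbouring AMP genes are detected by single-linkage chaining.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TE_CLASSES",
    "TEAnnotation",
    "GeneModel",
    "GeneTESummary",
    "resolve_te_overlaps",
    "intersect_genes_tes",
    "gene_structure_summary",
    "detect_clusters",
]

TE_CLASSES = (
    "DIRS", "DNA", "LINE", "LTR", "RC", "Retroposon", "SINE", "Unknown",
    "Simple_repeat", "Low_complexity",
)
_DISCARD_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


@dataclass(frozen=True)
class TEAnnotation:
    """One TE call: scaffold interval, strand, family, class, divergence (%)."""

    scaffold: str
    start: int
    end: int
    strand: str
    te_family: str
    te_class: str
    divergence: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed TE interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Scaffold-anchored gene with strand and ordered disjoint exons."""

    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    family_label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id!r}: empty span")
        if not self.exons:
            raise ValueError(f"gene {self.id!r}: needs at least one exon")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"gene {self.id!r}: invalid exon [{s}, {e})")
            prev = e

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GeneTESummary:
    """Intronic TE load of one gene."""

    gene_id: str
    te_count: int = 0
    te_total_length: int = 0
    per_class: dict[str, int] = field(default_factory=dict)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _merge(a: TEAnnotation, b: TEAnnotation) -> TEAnnotation:
    keeper = a if a.divergence <= b.divergence else b
    return replace(
        keeper, start=min(a.start, b.start), end=max(a.end, b.end)
    )


def resolve_te_overlaps(
    tes: Iterable[TEAnnotation],
    max_gap: int = 10,
    min_recip_cov: float = 0.80,
    coverage_mode: str = "longer",
    unresolved: str = "keep_lower_divergence",
) -> list[TEAnnotation]:
    """Collapse redundant same-strand TE calls.

    Rules, applied left-to-right on (scaffold, start)-sorted input until a
    fixpoint:

    1. Simple-repeat / low-complexity records are removed first.
    2. Same-scaffold, same-strand pairs separated by at most ``max_gap`` bp
       (touching or overlapping included) are candidates.
    3. If the overlap covers at least ``min_recip_cov`` of the longer element
       (``coverage_mode="longer"``; ``"both"`` demands the fraction of each),
       the pair merges into the union interval, inheriting family, class and
       divergence from the lower-divergence member.
    4. Overlapping candidates failing (3) keep only the lower-divergence
       member (``unresolved="keep_both"`` disables the drop).
    5. Nearby but non-overlapping candidates failing (3) are both kept.
    """
    if coverage_mode not in ("longer", "both"):
        raise ValueError("coverage_mode must be 'longer' or 'both'")
    pool = [t for t in tes if t.te_class not in _DISCARD_CLASSES]

    def covered(a: TEAnnotation, b: TEAnnotation, ov: int) -> bool:
        if coverage_mode == "longer":
            return ov >= min_recip_cov * max(a.length, b.length)
        return ov >= min_recip_cov * a.length and ov >= min_recip_cov * b.length

    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda t: (t.scaffold, t.start, t.end))
        out: list[TEAnnotation] = []
        for te in pool:
            current: TEAnnotation | None = te
            while current is not None and out:
                prev = out[-1]
                if prev.scaffold != current.scaffold or prev.strand != current.strand:
                    break
                gap = current.start - prev.end
                if gap > max_gap:
                    break
                ov = _overlap(prev.start, prev.end, current.start, current.end)
                if covered(prev, current, ov):
                    out.pop()
                    current = _merge(prev, current)
                    changed = True
                    continue  # union may chain into the element before it
                if ov > 0 and unresolved == "keep_lower_divergence":
                    changed = True
                    if current.divergence < prev.divergence:
                        out.pop()
                        continue  # re-test against the element before prev
                    current = None  # higher-divergence newcomer dropped
                    break
                break  # nearby but non-overlapping: keep both
            if current is not None:
                out.append(current)
        pool = out
    return pool


def intersect_genes_tes(
    genes: Sequence[GeneModel],
    resolved_tes: Sequence[TEAnnotation],
) -> tuple[list[GeneTESummary], pd.DataFrame]:
    """Intersect gene spans with TEs; summarise the intronic TE load per gene.

    A TE counts for a gene when it overlaps the gene span by >= 1 bp; its
    contribution to ``te_total_length`` is clipped to the gene span.  TEs
    overlapping any exon are tagged ``exonic`` and excluded from the intronic
    summary.  Returns (per-gene summaries, per-overlap tag table).
    """
    summaries = []
    rows = []
    by_scaffold: dict[str, list[TEAnnotation]] = {}
    for te in resolved_tes:
        by_scaffold.setdefault(te.scaffold, []).append(te)
    for gene in genes:
        summary = GeneTESummary(gene_id=gene.id)
        for te in by_scaffold.get(gene.scaffold, []):
            ov = _overlap(gene.start, gene.end, te.start, te.end)
            if ov == 0:
                continue
            exonic = any(_overlap(s, e, te.start, te.end) > 0 for s, e in gene.exons)
            rows.append(
                {
                    "gene_id": gene.id,
                    "te_family": te.te_family,
                    "te_class": te.te_class,
                    "start": te.start,
                    "end": te.end,
                    "overlap_bp": ov,
                    "location": "exonic" if exonic else "intronic",
                }
            )
            if not exonic:
                summary.te_count += 1
                summary.te_total_length += ov
                summary.per_class[te.te_class] = (
                    summary.per_class.get(te.te_class, 0) + 1
                )
        summaries.append(summary)
    columns = ["gene_id", "te_family", "te_class", "start", "end",
               "overlap_bp", "location"]
    return summaries, pd.DataFrame(rows, columns=columns)


def _sigfig2(x: float) -> float:
    """Round to 2 significant figures (display convention for percentages)."""
    if x == 0:
        return 0.0
    return float(f"{x:.2g}")


def gene_structure_summary(
    genes: Sequence[GeneModel],
    full_length_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Per-family exon-count spectrum and gene-length statistics.

    Optionally restrict to genes whose ids appear in ``full_length_ids``
    (those coding full precursor peptides).  Percentages are computed against
    per-family totals and rounded to 2 significant figures; gene length is
    reported as median with (min - max) range.
    """
    pool = [g for g in genes if g.family_label is not None]
    if full_length_ids is not None:
        pool = [g for g in pool if g.id in full_length_ids]
    rows = []
    families = sorted({g.family_label for g in pool})
    for fam in families:
        members = [g for g in pool if g.family_label == fam]
        spans = np.array([g.span for g in members])
        counts: dict[int, int] = {}
        for g in members:
            counts[len(g.exons)] = counts.get(len(g.exons), 0) + 1
        for n_exons in sorted(counts):
            rows.append(
                {
                    "family": fam,
                    "n_genes": len(members),
                    "exons": n_exons,
                    "count": counts[n_exons],
                    "percent": _sigfig2(100.0 * counts[n_exons] / len(members)),
                    "length_median": float(np.median(spans)),
                    "length_min": int(spans.min()),
                    "length_max": int(spans.max()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["family", "n_genes", "exons", "count", "percent",
                 "length_median", "length_min", "length_max"],
    )


def detect_clusters(
    genes: Sequence[GeneModel],
    max_gap_bp: int = 10_000,
) -> list[list[str]]:
    """Single-linkage gene clusters per scaffold.

    Consecutive genes on the same scaffold chain into a cluster when the gap
    between them (next.start - prev.end) is at most ``max_gap_bp``.  Only
    clusters of two or more genes are reported; singletons are omitted.  The
    10 kb default is the upper bound of the observed AMP cluster extents.
    """
    clusters: list[list[str]] = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold in sorted(by_scaffold):
        members = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end))
        current = [members[0]]
        for g in members[1:]:
            if g.start - current[-1].end <= max_gap_bp:
                current.append(g)
            else:
                if len(current) > 1:
                    clusters.append([x.id for x in current])
                current = [g]
        if len(current) > 1:
            clusters.append([x.id for x in current])
    return clusters
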