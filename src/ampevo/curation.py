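"""Sequence-level curation of antimicrobial-peptide candidates.

Defensins and cathelicidins are short secreted peptides recognisable by a
conserved cysteine scaffold: six cysteines for the defensins (three disulfide
bridges) and four for the cathelin propeptide of cathelicidins.  This module
codifies the manual screening steps applied to candidate peptide sets —
length window, standard alphabet, premature stop codons, minimum cysteine
content, exact-duplicate removal — and the motif-class call used to route a
peptide to a family-specific analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STANDARD_AA",
    "PeptideRecord",
    "RejectReason",
    "FilterReport",
    "filter_peptides",
    "cysteine_motif_class",
    "filter_genes_by_length",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideRecord:
    """A protein sequence with optional precursor-region annotations.

    Parameters
    ----------
    id : str
        Sequence identifier.
    sequence : str
        Amino-acid sequence (one-letter codes). A single trailing ``*``
        (translated terminal stop) is tolerated and stripped by the filters.
    source_tag : str
        Free-text provenance label (e.g. species or database of origin).
    regions : mapping, optional
        Maps any of ``{"signal", "propeptide", "mature"}`` to half-open
        ``(start, end)`` index ranges into ``sequence``.
    """

    id: str
    sequence: str
    source_tag: str = ""
    regions: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.regions:
            prev_end = 0
            for name in ("signal", "propeptide", "mature"):
                if name not in self.regions:
                    continue
                start, end = self.regions[name]
                if not (0 <= start <= end <= len(self.sequence)):
                    raise ValueError(
                        f"region {name!r} out of bounds for record {self.id!r}"
                    )
                if start < prev_end:
                    raise ValueError(
                        f"region {name!r} overlaps a preceding region "
                        f"in record {self.id!r}"
                    )
                prev_end = end

    def region_sequence(self, name: str) -> str | None:
        """Return the subsequence for a named region, or None if unannotated."""
        if not self.regions or name not in self.regions:
            return None
        start, end = self.regions[name]
        return self.sequence[start:end]


class RejectReason(str, Enum):
    """Why a peptide was removed, in predicate order."""

    TOO_SHORT = "too_short"
    TOO_LONG = "too_long"
    NONSTANDARD_AA = "nonstandard_aa"
    INTERNAL_STOP = "internal_stop"
    LOW_CYSTEINE = "low_cysteine"
    DUPLICATE = "duplicate"


@dataclass
class FilterReport:
    """Outcome of :func:`filter_peptides`: kept records and per-record reasons."""

    kept: list[PeptideRecord] = field(default_factory=list)
    rejected: list[tuple[PeptideRecord, RejectReason]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_rows(self) -> list[tuple[str, str]]:
        """(id, reason) rows for the rejection TSV; kept records report 'kept'."""
        rows = [(r.id, "kept") for r in self.kept]
        rows += [(r.id, reason.value) for r, reason in self.rejected]
        return rows


def _clean(sequence: str) -> str:
    """Uppercase and strip one trailing translated stop."""
    seq = sequence.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return seq


def filter_peptides(
    records: Iterable[PeptideRecord],
    min_len: int = 10,
    max_len: int = 200,
    min_cys: int = 2,
    dedup: bool = True,
) -> FilterReport:
    """Apply the curation predicates in documented order.

    Order: length (too short, then too long), standard alphabet, internal
    stop codon, cysteine count, exact-sequence duplicate.  The reported
    rejection reason is the first failing predicate.  Duplicates key on the
    uppercased sequence; the first occurrence is kept.  Defaults mirror the
    curation windows used for bat AMP candidates: 10-200 residues, at least
    two cysteines.
    """
    if min_len <= 0 or max_len <= 0 or min_cys < 0:
        raise ValueError("filter parameters must be positive")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")

    report = FilterReport()
    seen: set[str] = set()
    for record in records:
        seq = _clean(record.sequence)
        reason: RejectReason | None = None
        if len(seq) < min_len:
            reason = RejectReason.TOO_SHORT
        elif len(seq) > max_len:
            reason = RejectReason.TOO_LONG
        elif "*" in seq:
            reason = RejectReason.INTERNAL_STOP
        elif not set(seq) <= STANDARD_AA:
            reason = RejectReason.NONSTANDARD_AA
        elif seq.count("C") < min_cys:
            reason = RejectReason.LOW_CYSTEINE
        elif dedup and seq in seen:
            reason = RejectReason.DUPLICATE
        if reason is None:
            seen.add(seq)
            report.kept.append(record)
        else:
            report.rejected.append((record, reason))
    return report


def cysteine_motif_class(
    record: PeptideRecord,
    region: str = "mature-if-annotated-else-full",
    defensin_min: int = 6,
    cathelicidin_range: tuple[int, int] = (4, 5),
) -> str:
    """Classify a peptide by its cysteine scaffold.

    Returns ``"defensin6"`` when the examined region carries at least
    ``defensin_min`` cysteines, ``"cathelicidin4"`` when the count falls in
    ``cathelicidin_range`` (inclusive), else ``"none"``.  By default the
    mature region is examined when annotated (the disulfide scaffold lives
    there); otherwise the full sequence is used.
    """
    if region == "mature-if-annotated-else-full":
        seq = record.region_sequence("mature")
        if seq is None:
            seq = record.sequence
    elif region == "full":
        seq = record.sequence
    else:
        seq = record.region_sequence(region)
        if seq is None:
            raise ValueError(f"record {record.id!r} has no region {region!r}")
    n_cys = _clean(seq).count("C")
    if n_cys >= defensin_min:
        return "defensin6"
    lo, hi = cathelicidin_range
    if lo <= n_cys <= hi:
        return "cathelicidin4"
    return "none"


def filter_genes_by_length(genes: Sequence, min_nt: int = 200) -> list:
    """Keep gene models whose genomic span is at least ``min_nt`` bp.

    Shorter loci cannot encode a full precursor (signal + propeptide +
    mature); the 200 bp default keeps the boundary case.  Accepts any objects
    with ``start``/``end`` attributes (half-open coordinates).
    """
    return [g for g in genes if (g.end - g.start) >= min_nt]
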