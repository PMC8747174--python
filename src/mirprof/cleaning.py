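"""Read cleaning: adapter trimming, quality/length filters, tag collapsing,
ncRNA contaminant removal, and library summaries.

The cleaning contract is read-count conserving: every raw read ends up
either in the surviving tag set or in exactly one removal category of the
:class:`CleaningReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from mirprof.seqio import SmallRNARead, canonical, reverse_complement

logger = logging.getLogger(__name__)

#: deterministic contaminant class-attribution order
NCRNA_CLASS_ORDER = ("rRNA", "snoRNA", "snRNA", "tRNA")


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed small-RNA sequence (canonical DNA space) and its read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CleaningReport:
    """Per-stage accounting of a cleaning run, in raw-read units."""

    total_reads: int = 0
    trimmed_reads: int = 0
    removed_low_quality: int = 0
    removed_short_long: int = 0
    removed_by_class: dict[str, int] = field(default_factory=dict)
    surviving_reads: int = 0
    unique_tags: int = 0

    def check_conservation(self) -> None:
        removed = (
            self.removed_low_quality
            + self.removed_short_long
            + sum(self.removed_by_class.values())
        )
        if self.total_reads != self.surviving_reads + removed:
            raise AssertionError(
                f"read-count conservation violated: {self.total_reads} != "
                f"{self.surviving_reads} + {removed}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_reads", self.total_reads),
            ("trimmed_reads", self.trimmed_reads),
            ("removed_low_quality", self.removed_low_quality),
            ("removed_short_long", self.removed_short_long),
        ]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_class.items()]
        rows += [
            ("surviving_reads", self.surviving_reads),
            ("unique_tags", self.unique_tags),
        ]
        return pd.DataFrame(rows, columns=["category", "reads"])


def trim_adapter(read: SmallRNARead, adapter: str, min_overlap: int = 8) -> SmallRNARead:
    """Remove a 3' adapter from a read.

    The suffix starting at the leftmost position where >= ``min_overlap``
    characters of the adapter prefix match is removed; quality is truncated
    in lockstep. A read with no match is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = canonical(read.sequence)
    adapter = canonical(adapter)
    n, m = len(seq), len(adapter)
    cut = None
    for i in range(n):
        k = min(m, n - i)
        if k >= min_overlap and seq[i : i + k] == adapter[:k]:
            cut = i
            break
    if cut is None:
        return read
    return SmallRNARead(
        read.read_id,
        read.sequence[:cut],
        read.quality[:cut] if read.quality is not None else None,
    )


def quality_filter(read: SmallRNARead, min_mean_q: float = 30.0) -> bool:
    """Keep decision for a read: mean Phred >= ``min_mean_q``.

    FASTA reads (no quality) are kept; the pipeline driver logs a notice
    once when the stage is skipped for quality-less input.
    """
    if not read.quality:  # FASTA input, or empty post-trim read
        return True
    return sum(read.quality) / len(read.quality) >= min_mean_q


def collapse_unique(sequences: Iterable[str]) -> list[UniqueTag]:
    """Collapse canonicalized read sequences to unique tags with counts.

    Output ordering is deterministic: descending count, then sequence.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        counts[seq] = counts.get(seq, 0) + 1
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_filter(
    tags: Sequence[UniqueTag], min_len: int = 16, max_len: int = 40
) -> tuple[list[UniqueTag], int]:
    """Retain tags with ``min_len <= length <= max_len`` (inclusive bounds).

    Returns the retained tags and the number of *reads* removed.
    """
    kept, removed_reads = [], 0
    for tag in tags:
        if min_len <= len(tag) <= max_len:
            kept.append(tag)
        else:
            removed_reads += tag.count
    return kept, removed_reads


def remove_ncrna(
    tags: Sequence[UniqueTag],
    contaminants: Sequence[tuple[str, str, str]],
    max_mismatch: int = 0,
) -> tuple[list[UniqueTag], dict[str, int]]:
    """Remove tags contained in ncRNA contaminants (rRNA/tRNA/snRNA/snoRNA).

    ``contaminants`` is a sequence of ``(ncrna_class, record_id, sequence)``.
    A tag is removed when it occurs as a substring of a contaminant on
    either strand, allowing up to ``max_mismatch`` substitutions over a
    same-length window. When a tag matches several classes it is attributed
    to the first matching class in the fixed order rRNA, snoRNA, snRNA,
    tRNA, so removal counts are deterministic.

    Returns (kept tags, removed read counts per class).
    """
    by_class: dict[str, list[str]] = {}
    for cls, rec_id, seq in contaminants:
        if not cls:
            raise ValueError(f"contaminant {rec_id!r} lacks a class label")
        if cls not in NCRNA_CLASS_ORDER:
            raise ValueError(
                f"contaminant {rec_id!r}: unknown class {cls!r} "
                f"(expected one of {NCRNA_CLASS_ORDER})"
            )
        cseq = canonical(seq)
        by_class.setdefault(cls, []).extend([cseq, reverse_complement(cseq)])

    def hits(tag_seq: str, target: str) -> bool:
        if max_mismatch == 0:
            return tag_seq in target
        L = len(tag_seq)
        for i in range(len(target) - L + 1):
            mm = sum(a != b for a, b in zip(tag_seq, target[i : i + L]))
            if mm <= max_mismatch:
                return True
        return False

    kept: list[UniqueTag] = []
    removed: dict[str, int] = {cls: 0 for cls in NCRNA_CLASS_ORDER}
    for tag in tags:
        matched = None
        for cls in NCRNA_CLASS_ORDER:
            if any(hits(tag.sequence, target) for target in by_class.get(cls, ())):
                matched = cls
                break
        if matched is None:
            kept.append(tag)
        else:
            removed[matched] += tag.count
    return kept, removed


def length_distribution(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """Unique-tag length distribution over the retained 16-40 nt range.

    Percentages are of unique tags (not of read counts); the most abundant
    length is the table's argmax row.
    """
    counts: dict[int, int] = {}
    for tag in tags:
        counts[len(tag)] = counts.get(len(tag), 0) + 1
    total = sum(counts.values())
    rows = [
        (length, n, 100.0 * n / total if total else 0.0)
        for length, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["length", "tag_count", "percent"])


def clean_reads(
    reads: Sequence[SmallRNARead],
    adapter: Optional[str] = None,
    min_overlap: int = 8,
    min_mean_q: float = 30.0,
    min_len: int = 16,
    max_len: int = 40,
    contaminants: Sequence[tuple[str, str, str]] = (),
    max_mismatch: int = 0,
) -> tuple[list[UniqueTag], CleaningReport]:
    """Full cleaning pipeline: trim -> Q filter -> collapse -> length -> ncRNA.

    Returns the surviving unique tags and a conservation-checked report.
    """
    report = CleaningReport(total_reads=len(reads))
    if reads and reads[0].quality is None:
        logger.info("input has no quality scores; quality filter skipped")

    surviving_seqs: list[str] = []
    for read in reads:
        trimmed = trim_adapter(read, adapter, min_overlap) if adapter else read
        if trimmed is not read:
            report.trimmed_reads += 1
        if not quality_filter(trimmed, min_mean_q):
            report.removed_low_quality += 1
            continue
        surviving_seqs.append(canonical(trimmed.sequence))

    tags = collapse_unique(s for s in surviving_seqs if s)
    report.removed_short_long += sum(1 for s in surviving_seqs if not s)
    tags, removed_len = length_filter(tags, min_len, max_len)
    report.removed_short_long = removed_len

    tags, removed_cls = remove_ncrna(tags, contaminants, max_mismatch)
    report.removed_by_class = removed_cls
    report.surviving_reads = sum(tag.count for tag in tags)
    report.unique_tags = len(tags)
    report.check_conservation()
    return tags, report


def tags_to_fasta(tags: Sequence[UniqueTag], path) -> None:
    """Write collapsed tags as FASTA with ``tag<N>_x<count>`` headers."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")


def tags_from_fasta(path) -> list[UniqueTag]:
    """Read a collapsed-tag FASTA; counts from ``_x<count>`` header suffixes
    (headers without the suffix count as 1)."""
    from mirprof.seqio import read_sequences

    tags = []
    for rec in read_sequences(path, format="fasta"):
        count = 1
        if "_x" in rec.read_id:
            suffix = rec.read_id.rsplit("_x", 1)[1]
            if suffix.isdigit():
                count = int(suffix)
        tags.append(UniqueTag(canonical(rec.sequence), count))
    return tags
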