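"""Conserved miRNA annotation by ungapped homology to a mature reference set.

A cleaned unique tag is called conserved when its best ungapped,
substitution-only alignment to any reference mature miRNA has at most
``max_mismatch`` (default 1) mismatches, with the shorter sequence fully
contained in the longer and overhangs free. This mirrors the mismatch
vocabulary of miRBase-style homology searches while staying exact and
deterministic (no heuristic seeding).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from mirprof.cleaning import UniqueTag
from mirprof.seqio import ReferenceMatureRecord, canonical


@dataclass(frozen=True)
class ConservedAssignment:
    """A tag assigned to its best-matching reference mature miRNA."""

    tag_sequence: str
    ref_id: str
    family: Optional[str]
    mismatches: int
    read_count: int
    assigned_name: str
    offset: int
    ambiguous_family: bool = False


def count_mismatches(tag: str, ref: str) -> tuple[int, int]:
    """Minimum ungapped substitution count between two sequences.

    The shorter sequence is slid fully inside the longer over every offset;
    overhanging bases of the longer sequence are free. Returns
    ``(mismatches, offset)`` where offset is the position of the tag
    relative to the reference 5' end (negative when the reference sits
    inside a longer tag). Ties are broken by smallest ``|offset|``, then by
    the negative offset.
    """
    t, r = canonical(tag), canonical(ref)
    if not t or not r:
        raise ValueError("empty sequence in mismatch count")
    flipped = False
    if len(t) > len(r):
        t, r = r, t
        flipped = True
    span = len(r) - len(t)
    best: tuple[int, int, int] | None = None  # (mm, |offset|, -sign key)
    best_offset = 0
    best_mm = len(t) + 1
    for off in range(span + 1):
        mm = sum(a != b for a, b in zip(t, r[off : off + len(t)]))
        signed = -off if flipped else off
        key = (mm, abs(signed), 0 if signed < 0 else 1)
        if best is None or key < best:
            best = key
            best_mm, best_offset = mm, signed
    return best_mm, best_offset


def _rename(ref_id: str, prefix: str = "mko") -> str:
    """Rename a reference id to the study species prefix (ath-miR159a -> mko-miR159a)."""
    m = re.match(r"^[a-z]{2,4}-(.+)$", ref_id)
    body = m.group(1) if m else ref_id
    return f"{prefix}-{body}"


def classify_conserved(
    tags: Sequence[UniqueTag],
    reference: Sequence[ReferenceMatureRecord],
    max_mismatch: int = 1,
    name_prefix: str = "mko",
) -> tuple[list[ConservedAssignment], list[UniqueTag]]:
    """Partition tags into conserved assignments and unassigned tags.

    Each tag is assigned to the reference with the fewest mismatches when
    that minimum is <= ``max_mismatch``; ties go to the lexicographically
    smallest ``ref_id``. When tied references disagree on family, the
    assignment is flagged ``ambiguous_family``. Unassigned tags feed novel
    discovery.
    """
    if not reference:
        raise ValueError("reference set is empty")
    assignments: list[ConservedAssignment] = []
    unassigned: list[UniqueTag] = []
    for tag in tags:
        best_mm = max_mismatch + 1
        best_ref: Optional[ReferenceMatureRecord] = None
        best_off = 0
        tied_families: set[Optional[str]] = set()
        for ref in sorted(reference, key=lambda r: r.ref_id):
            mm, off = count_mismatches(tag.sequence, ref.sequence)
            if mm < best_mm:
                best_mm, best_ref, best_off = mm, ref, off
                tied_families = {ref.family}
            elif mm == best_mm and best_ref is not None:
                tied_families.add(ref.family)
        if best_ref is None or best_mm > max_mismatch:
            unassigned.append(tag)
        else:
            assignments.append(
                ConservedAssignment(
                    tag_sequence=tag.sequence,
                    ref_id=best_ref.ref_id,
                    family=best_ref.family,
                    mismatches=best_mm,
                    read_count=tag.count,
                    assigned_name=_rename(best_ref.ref_id, name_prefix),
                    offset=best_off,
                    ambiguous_family=len(tied_families) > 1,
                )
            )
    return assignments, unassigned


def assignments_to_frame(assignments: Sequence[ConservedAssignment]) -> pd.DataFrame:
    """Tabulate assignments in the conserved-summary column layout."""
    return pd.DataFrame(
        [
            {
                "family": a.family if a.family is not None else "NA",
                "name": a.assigned_name,
                "sequence": a.tag_sequence,
                "length_nt": len(a.tag_sequence),
                "reference_mirna": a.ref_id,
                "mismatches": a.mismatches,
                "read_count": a.read_count,
                "ambiguous_family": a.ambiguous_family,
            }
            for a in assignments
        ]
    )


def summarize_families(table: pd.DataFrame) -> pd.DataFrame:
    """Per-family member counts and total reads.

    ``table`` needs columns family / sequence / read_count (as produced by
    :func:`assignments_to_frame` or the packaged conserved fixture). A
    family's member count is its number of distinct member sequences
    (names may legitimately repeat across sequence variants); rows with
    family ``NA`` are grouped under ``NA`` but excluded from family-count
    statistics by callers. Ordered by descending total reads.
    """
    grouped = (
        table.groupby("family", sort=False)
        .agg(
            member_count=("sequence", "nunique"),
            total_reads=("read_count", "sum"),
        )
        .reset_index()
        .sort_values(["total_reads", "family"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return grouped
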