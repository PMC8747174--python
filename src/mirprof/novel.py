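"""Novel miRNA discovery from unassigned tags.

Tags that fail conserved annotation are mapped to a reference genome
(exact or near-exact, ungapped), candidate precursor windows are excised
around each hit, folded, and screened with stem-loop criteria; surviving
candidates are scored with AMFE and the minimal folding free energy index
MFEI = AMFE / GC%, where AMFE = (|MFE| / precursor length) x 100. Calls are
gated on MFEI >= 0.70 and a read-count (copy number) floor, both
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from mirprof.cleaning import UniqueTag
from mirprof.fold import fold, gc_percent, pairs_from_structure
from mirprof.seqio import canonical, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeHit:
    """An ungapped genomic match of a tag."""

    tag_sequence: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class PrecursorCandidate:
    """An excised, folded precursor window around a genomic tag hit."""

    sequence: str
    window: tuple[str, int, int, str]  # contig, start, end, strand
    structure: str
    mfe: float
    amfe: float
    gc_percent: float
    mfei: float
    mature_offset: int  # 0-based position of the mature within `sequence`
    mature_length: int
    read_count: int
    mature_arm: Optional[str] = None  # '5p' / '3p' when the hairpin test passes
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.mature_length]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def map_to_genome(
    tags: Sequence[UniqueTag],
    genome: dict[str, str],
    max_mismatch: int = 0,
) -> list[GenomeHit]:
    """Find all ungapped genomic matches of each tag on both strands.

    Substitutions only (up to ``max_mismatch``); hits are ordered by
    (contig, start, strand) and coordinates always refer to the forward
    strand of the contig.
    """
    if max_mismatch > 2:
        raise ValueError("mapping budget above 2 mismatches is not supported")
    hits: list[GenomeHit] = []
    encoded = {name: _encode(canonical(seq)) for name, seq in genome.items()}
    for tag in tags:
        tseq = canonical(tag.sequence)
        L = len(tseq)
        queries = {"+": _encode(tseq), "-": _encode(reverse_complement(tseq))}
        for contig in sorted(encoded):
            g = encoded[contig]
            if len(g) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, L)
            for strand, q in queries.items():
                mm = (windows != q).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    hits.append(
                        GenomeHit(
                            tag_sequence=tseq,
                            contig=contig,
                            start=int(pos),
                            end=int(pos) + L,
                            strand=strand,
                            mismatches=int(mm[pos]),
                        )
                    )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand, h.tag_sequence))
    return hits


def excise_precursors(
    hit: GenomeHit,
    genome: dict[str, str],
    flank: int = 150,
    min_loop: int = 3,
) -> list[tuple[str, tuple[str, int, int, str], int]]:
    """Excise up to two candidate precursor windows around a genomic hit.

    Windows are ``[start - flank, end + 20)`` (mature on the 3' side of a
    long 5' flank) and ``[start - 20, end + flank)``, clipped to contig
    bounds. Minus-strand windows are reverse complemented so the returned
    sequence reads 5'->3' with the mature in tag orientation. Each entry is
    ``(sequence, (contig, start, end, strand), mature_offset)``. Windows too
    short to host a hairpin (< tag + 2 * min_loop) are discarded.
    """
    if flank < 20:
        raise ValueError("flank must be >= 20")
    contig_seq = canonical(genome[hit.contig])
    n = len(contig_seq)
    L = hit.end - hit.start
    out = []
    spans = {(max(0, hit.start - flank), min(n, hit.end + 20)),
             (max(0, hit.start - 20), min(n, hit.end + flank))}
    for wstart, wend in sorted(spans):
        wlen = wend - wstart
        if wlen < L + 2 * min_loop:
            logger.info(
                "window %s:%d-%d too short for a hairpin; discarded", hit.contig, wstart, wend
            )
            continue
        seq = contig_seq[wstart:wend]
        if hit.strand == "+":
            offset = hit.start - wstart
        else:
            seq = reverse_complement(seq)
            offset = wend - hit.end
        out.append((seq, (hit.contig, wstart, wend, hit.strand), offset))
    return out


def compute_mfei(mfe: float, length: int, gc_pct: float) -> tuple[float, float]:
    """AMFE and MFEI from a fold energy.

    AMFE = (|MFE| / length) x 100 (kcal/mol per 100 nt); MFEI = AMFE / GC%
    with GC on the 0-100 scale, so MFEI is dimensionless and >= 0.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 < gc_pct < 100.0):
        raise ValueError(f"GC percent {gc_pct} outside (0, 100); MFEI undefined")
    amfe = abs(mfe) / length * 100.0
    return amfe, amfe / gc_pct


def _terminal_loops(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Loop intervals (i+1, j-1) of hairpin-closing pairs (no pair inside)."""
    loops = []
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs):
            loops.append((i + 1, j - 1))
    return loops


def hairpin_criteria(
    structure: str,
    mature_offset: int,
    mature_length: int,
    min_paired_mature: int = 16,
    max_arm_bulge: int = 4,
    min_stem_pairs: int = 18,
) -> tuple[bool, list[str], Optional[str]]:
    """Stem-loop screen for a folded precursor window.

    Pass requires: the mature lies entirely on one arm (no terminal-loop
    overlap, all base-pair partners on one side); at least
    ``min_paired_mature`` mature bases paired with no unpaired run longer
    than ``max_arm_bulge``; the helix containing the mature closes exactly
    one terminal loop (single stem-loop); and the stem enclosing the mature
    holds at least ``min_stem_pairs`` base pairs. Returns
    ``(passed, failure reasons, arm)`` with arm '5p'/'3p' when determined.
    """
    pairs = pairs_from_structure(structure)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    m_lo, m_hi = mature_offset, mature_offset + mature_length  # [lo, hi)
    reasons: list[str] = []

    loops = _terminal_loops(pairs)
    if any(lo < m_hi and m_lo <= hi for lo, hi in loops):
        reasons.append("loop overlap")

    mature_pairs = [(i, partner[i]) for i in range(m_lo, m_hi) if i in partner]
    n_paired = len(mature_pairs)
    if n_paired < min_paired_mature:
        reasons.append("insufficient mature pairing")

    # longest unpaired run inside the mature
    run = best_run = 0
    for i in range(m_lo, m_hi):
        run = run + 1 if i not in partner else 0
        best_run = max(best_run, run)
    if best_run > max_arm_bulge:
        reasons.append("large bulge")

    arm: Optional[str] = None
    if mature_pairs:
        if all(j >= m_hi for _, j in mature_pairs):
            arm = "5p"
        elif all(j < m_lo for _, j in mature_pairs):
            arm = "3p"
        else:
            reasons.append("mature spans both arms")

    if arm is not None and "loop overlap" not in reasons:
        inner = min(mature_pairs, key=lambda p: abs(p[1] - p[0]))
        a, b = min(inner), max(inner)
        n_loops = sum(1 for lo, hi in loops if a < lo and hi < b)
        if n_loops != 1:
            reasons.append("branched structure")
        outer = max(mature_pairs, key=lambda p: abs(p[1] - p[0]))
        a0, b0 = min(outer), max(outer)
        stem_pairs = sum(1 for i, j in pairs if a0 <= i and j <= b0)
        if stem_pairs < min_stem_pairs:
            reasons.append("short stem")

    return (not reasons, reasons, arm)


def evaluate_candidate(
    window_seq: str,
    window: tuple[str, int, int, str],
    mature_offset: int,
    mature_length: int,
    read_count: int,
    fold_engine: Callable[[str], tuple[str, float]] = fold,
    min_paired_mature: int = 16,
    max_arm_bulge: int = 4,
    min_stem_pairs: int = 18,
) -> PrecursorCandidate:
    """Fold a window and score it as a precursor candidate."""
    structure, mfe = fold_engine(window_seq)
    gc = gc_percent(window_seq)
    amfe, mfei = compute_mfei(mfe, len(window_seq), gc)
    passed, reasons, arm = hairpin_criteria(
        structure,
        mature_offset,
        mature_length,
        min_paired_mature=min_paired_mature,
        max_arm_bulge=max_arm_bulge,
        min_stem_pairs=min_stem_pairs,
    )
    return PrecursorCandidate(
        sequence=window_seq,
        window=window,
        structure=structure,
        mfe=mfe,
        amfe=amfe,
        gc_percent=gc,
        mfei=mfei,
        mature_offset=mature_offset,
        mature_length=mature_length,
        read_count=read_count,
        mature_arm=arm,
        passed=passed,
        fail_reasons=reasons,
    )


def call_novel(
    candidates: Sequence[PrecursorCandidate],
    mfei_threshold: float = 0.70,
    copy_threshold: int = 5,
    name_prefix: str = "mko",
) -> pd.DataFrame:
    """Gate passing candidates on MFEI and copy number and name the calls.

    Multiple genomic loci of the same mature collapse to the max-MFEI
    locus. Names are assigned ``<prefix>-miRN<k>-<arm>`` in descending
    read-count order (ties by sequence). Boundary values are retained:
    MFEI exactly at the threshold and read counts exactly at the floor pass.
    """
    surviving = [
        c
        for c in candidates
        if c.passed and c.mfei >= mfei_threshold and c.read_count >= copy_threshold
    ]
    best_by_mature: dict[str, PrecursorCandidate] = {}
    for cand in surviving:
        cur = best_by_mature.get(cand.mature_sequence)
        if cur is None or cand.mfei > cur.mfei:
            best_by_mature[cand.mature_sequence] = cand
    ordered = sorted(
        best_by_mature.values(), key=lambda c: (-c.read_count, c.mature_sequence)
    )
    rows = []
    for k, cand in enumerate(ordered, start=1):
        rows.append(
            {
                "name": f"{name_prefix}-miRN{k}-{cand.mature_arm}",
                "sequence": cand.mature_sequence,
                "length_nt": cand.mature_length,
                "read_count": cand.read_count,
                "strand": cand.window[3],
                "mfei": round(cand.mfei, 2),
                "amfe": round(cand.amfe, 2),
                "mfe": round(cand.mfe, 2),
                "gc_percent": round(cand.gc_percent, 2),
                "contig": cand.window[0],
                "window_start": cand.window[1],
                "window_end": cand.window[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "sequence", "length_nt", "read_count", "strand", "mfei",
            "amfe", "mfe", "gc_percent", "contig", "window_start", "window_end",
        ],
    )


def discover_novel(
    tags: Sequence[UniqueTag],
    genome: dict[str, str],
    max_mismatch: int = 0,
    flank: int = 150,
    fold_engine: Callable[[str], tuple[str, float]] = fold,
    mfei_threshold: float = 0.70,
    copy_threshold: int = 5,
    min_paired_mature: int = 16,
    max_arm_bulge: int = 4,
    min_stem_pairs: int = 18,
    name_prefix: str = "mko",
) -> tuple[pd.DataFrame, list[PrecursorCandidate]]:
    """End-to-end novel miRNA calling: map, excise, fold, screen, gate.

    Per genomic hit the best passing window (highest MFEI) is retained.
    Returns the calls table and every evaluated candidate (for reporting).
    """
    hits = map_to_genome(tags, genome, max_mismatch=max_mismatch)
    counts = {canonical(t.sequence): t.count for t in tags}
    all_cands: list[PrecursorCandidate] = []
    per_hit_best: list[PrecursorCandidate] = []
    for hit in hits:
        windows = excise_precursors(hit, genome, flank=flank)
        evaluated = [
            evaluate_candidate(
                seq,
                window,
                offset,
                hit.end - hit.start,
                counts[hit.tag_sequence],
                fold_engine=fold_engine,
                min_paired_mature=min_paired_mature,
                max_arm_bulge=max_arm_bulge,
                min_stem_pairs=min_stem_pairs,
            )
            for seq, window, offset in windows
        ]
        all_cands.extend(evaluated)
        passing = [c for c in evaluated if c.passed]
        if passing:
            per_hit_best.append(max(passing, key=lambda c: c.mfei))
    calls = call_novel(
        per_hit_best,
        mfei_threshold=mfei_threshold,
        copy_threshold=copy_threshold,
        name_prefix=name_prefix,
    )
    return calls, all_cands


def write_structures(candidates: Sequence[PrecursorCandidate], path) -> None:
    """Write precursor structures in Vienna format (sequence / structure (mfe))."""
    with open(path, "w") as fh:
        for cand in candidates:
            contig, start, end, strand = cand.window
            fh.write(f">{contig}:{start}-{end}({strand})\n")
            fh.write(cand.sequence + "\n")
            fh.write(f"{cand.structure} ({cand.mfe:.2f})\n")
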