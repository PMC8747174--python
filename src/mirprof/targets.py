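"""miRNA target prediction.

Two scanners are provided. Plant mode scores the reverse-complement
alignment of the miRNA against every same-length transcript window with an
expectation penalty (mismatch 1.0, G:U wobble 0.5, penalties doubled over
miRNA positions 2-13) and keeps the best site per transcript under a
cutoff; silencing mode is called from central complementarity (any
imperfection at miRNA positions 9-11 implies translational repression,
otherwise transcript cleavage). Cross-kingdom (animal) mode requires a
perfect Watson-Crick seed (miRNA positions 2-8) and filters sites on
hybridization energy |dG| >= 25 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from mirprof.fold import duplex_energy
from mirprof.seqio import canonical, reverse_complement

#: per-position alignment codes: '|' Watson-Crick pair, 'o' G:U wobble, '.' mismatch
MATCH, WOBBLE, MISMATCH = "|", "o", "."

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "T"), ("T", "G")}


@dataclass
class PenaltyScheme:
    """psRNATarget-style expectation penalties (all config-exposed)."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0  # retained for configurability; the default scanner is ungapped
    seed_start: int = 2  # 1-based miRNA positions with doubled penalties
    seed_end: int = 13
    seed_multiplier: float = 2.0


@dataclass
class TargetHit:
    """A scored miRNA-transcript interaction site."""

    mirna_name: str
    transcript_id: str
    alignment: str  # per-miRNA-position codes, position 1 first
    expectation: float
    duplex_energy: Optional[float]
    mode: Optional[str]  # 'cleavage' | 'translation'
    target_start: int  # 1-based inclusive
    target_end: int


def _align_codes(mirna: str, site: str) -> str:
    """Alignment codes for miRNA (5'->3') vs a same-length target site (5'->3').

    miRNA position k (1-based, from the miRNA 5' end) faces the target base
    ``site[L - k]`` (antiparallel pairing).
    """
    L = len(mirna)
    codes = []
    for k in range(L):
        a, b = mirna[k], site[L - 1 - k]
        if (a, b) in _WC:
            codes.append(MATCH)
        elif (a, b) in _WOB:
            codes.append(WOBBLE)
        else:
            codes.append(MISMATCH)
    return "".join(codes)


def expectation_score(alignment: str, scheme: PenaltyScheme = PenaltyScheme()) -> float:
    """Total expectation penalty of an alignment-code string."""
    total = 0.0
    for k, code in enumerate(alignment, start=1):
        if code == MATCH:
            continue
        pen = scheme.wobble if code == WOBBLE else scheme.mismatch
        if scheme.seed_start <= k <= scheme.seed_end:
            pen *= scheme.seed_multiplier
        total += pen
    return total


def call_mode(hit: TargetHit, central_start: int = 9, central_end: int = 11) -> str:
    """Silencing mode: translation iff any central position (9-11) is imperfect."""
    central = hit.alignment[central_start - 1 : central_end]
    return "translation" if any(c != MATCH for c in central) else "cleavage"


def plant_target_scan(
    mirna: str,
    transcripts: dict[str, str] | Sequence[tuple[str, str]],
    expectation_cutoff: float = 5.0,
    scheme: PenaltyScheme = PenaltyScheme(),
    mirna_name: str = "miRNA",
    compute_energy: bool = True,
) -> list[TargetHit]:
    """Plant-mode complementarity scan.

    Every same-length window of every transcript is scored; the best
    (lowest-expectation) site per transcript is emitted when its
    expectation is <= ``expectation_cutoff``, ties broken by the 5'-most
    target position. Silencing mode and (optionally) duplex energy are
    attached to each emitted hit.
    """
    m = canonical(mirna)
    if not (18 <= len(m) <= 26):
        raise ValueError(f"miRNA length {len(m)} outside 18-26 nt")
    items = transcripts.items() if isinstance(transcripts, dict) else transcripts
    hits: list[TargetHit] = []
    L = len(m)
    for tid, tseq in items:
        t = canonical(tseq)
        best: Optional[tuple[float, int, str]] = None
        for start in range(0, len(t) - L + 1):
            aln = _align_codes(m, t[start : start + L])
            exp = expectation_score(aln, scheme)
            if best is None or exp < best[0]:
                best = (exp, start, aln)
        if best is None or best[0] > expectation_cutoff:
            continue
        exp, start, aln = best
        site = t[start : start + L]
        hit = TargetHit(
            mirna_name=mirna_name,
            transcript_id=tid,
            alignment=aln,
            expectation=exp,
            duplex_energy=duplex_energy(m, site) if compute_energy else None,
            mode=None,
            target_start=start + 1,
            target_end=start + L,
        )
        hit.mode = call_mode(hit)
        hits.append(hit)
    return hits


def cross_kingdom_scan(
    mirna: str,
    transcripts: dict[str, str] | Sequence[tuple[str, str]],
    energy_cutoff_abs: float = 25.0,
    mirna_name: str = "miRNA",
    literal_energy_rule: bool = False,
) -> list[TargetHit]:
    """Animal-mode (strict seed) scan for cross-kingdom targets.

    Candidate sites must pair miRNA seed positions 2-8 by perfect
    Watson-Crick complementarity (wobbles rejected); surviving sites are
    filtered on hybridization energy |dG| >= ``energy_cutoff_abs`` kcal/mol
    (``literal_energy_rule`` switches to the literal reading
    dG >= -cutoff, admitting weak duplexes). The strongest surviving site
    per transcript is emitted.
    """
    m = canonical(mirna)
    items = transcripts.items() if isinstance(transcripts, dict) else transcripts
    L = len(m)
    hits: list[TargetHit] = []
    for tid, tseq in items:
        t = canonical(tseq)
        best: Optional[TargetHit] = None
        for start in range(0, len(t) - L + 1):
            site = t[start : start + L]
            aln = _align_codes(m, site)
            if any(aln[k - 1] != MATCH for k in range(2, 9)):
                continue
            energy = duplex_energy(m, site)
            if literal_energy_rule:
                ok = energy >= -energy_cutoff_abs
            else:
                ok = abs(energy) >= energy_cutoff_abs
            if not ok:
                continue
            hit = TargetHit(
                mirna_name=mirna_name,
                transcript_id=tid,
                alignment=aln,
                expectation=expectation_score(aln),
                duplex_energy=energy,
                mode=None,
                target_start=start + 1,
                target_end=start + L,
            )
            hit.mode = call_mode(hit)
            if best is None or hit.duplex_energy < best.duplex_energy:
                best = hit
        if best is not None:
            hits.append(best)
    return hits


def hits_to_frame(hits: Sequence[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": h.mirna_name,
                "transcript": h.transcript_id,
                "target_start": h.target_start,
                "target_end": h.target_end,
                "expectation": h.expectation,
                "duplex_energy": h.duplex_energy,
                "mode": h.mode,
                "alignment": h.alignment,
            }
            for h in hits
        ],
        columns=[
            "mirna", "transcript", "target_start", "target_end",
            "expectation", "duplex_energy", "mode", "alignment",
        ],
    )


def export_network(
    hits: Sequence[TargetHit], path, weak_cutoff: float = -15.0
) -> pd.DataFrame:
    """Write an MFE-weighted edge list (one edge per hit) as TSV.

    Edge weight is the duplex energy; edges weaker (less negative) than
    ``weak_cutoff`` are flagged so a network viewer can render them dashed.
    """
    df = pd.DataFrame(
        [
            {
                "source": h.mirna_name,
                "target": h.transcript_id,
                "weight": h.duplex_energy,
                "weak_flag": bool(h.duplex_energy is not None and h.duplex_energy > weak_cutoff),
            }
            for h in hits
        ],
        columns=["source", "target", "weight", "weak_flag"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def mode_fractions(hits: Sequence[TargetHit]) -> dict[str, float]:
    """Fraction of emitted hits per silencing mode (exhaustive partition)."""
    if not hits:
        return {"cleavage": 0.0, "translation": 0.0}
    n = len(hits)
    n_cleave = sum(1 for h in hits if h.mode == "cleavage")
    return {"cleavage": n_cleave / n, "translation": (n - n_cleave) / n}
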