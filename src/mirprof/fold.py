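"""RNA secondary-structure folding and duplex hybridization energies.

The bundled engine is a dynamic-programming fold over *stem-loop forests*:
a structure is any set of nested base pairs in which every closed pair
encloses at most one branch (simple stems with bulges and interior loops;
no multibranch loops), and the external region may carry any number of
adjacent stems. This structure space matches the engine's purpose --
evaluating miRNA precursor hairpins -- and keeps the fold exactly
solvable in O(n^2 * b^2) for bulge budget b.

Energy model (kcal/mol, all configurable through :class:`FoldParams`):
pair energies G:C -3.0, A:U -2.0 (optional G:U wobble -1.0, off by default
so that a sequence and its exact reverse complement fold to the same
|MFE|); a stacking bonus for each directly stacked pair; a fixed penalty
per hairpin loop; a per-base penalty for interior-loop/bulge bases, with
at most ``max_bulge`` unpaired bases per interior loop. MFE is always
<= 0 (the empty structure is admissible); a sequence with no admissible
pairs folds to all dots at 0. An external thermodynamic engine
(ViennaRNA) can be substituted through :func:`get_fold_engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from mirprof.seqio import canonical

#: default pair energies (kcal/mol) in canonical DNA space (U mapped to T)
PAIR_ENERGIES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
}
WOBBLE_ENERGIES = {("G", "T"): -1.0, ("T", "G"): -1.0}

MIN_LOOP = 3


@dataclass(frozen=True)
class FoldParams:
    """Tunable terms of the bundled fold energy model."""

    min_loop: int = MIN_LOOP  # minimum hairpin loop size, nt
    wobble: bool = False  # admit G:U pairs intramolecularly
    stack_bonus: float = -1.0  # per directly stacked pair
    hairpin_penalty: float = 3.0  # per terminal (hairpin) loop
    bulge_penalty: float = 0.5  # per unpaired base in an interior loop/bulge
    max_bulge: int = 8  # max unpaired bases per interior loop (both sides)


DEFAULT_PARAMS = FoldParams()


def _pair_energy_table(wobble: bool) -> dict[tuple[str, str], float]:
    table = dict(PAIR_ENERGIES)
    if wobble:
        table.update(WOBBLE_ENERGIES)
    return table


def fold(
    sequence: str, min_loop: int = MIN_LOOP, wobble: bool = False,
    params: FoldParams | None = None,
) -> tuple[str, float]:
    """Fold a sequence, returning (dot-bracket structure, MFE in kcal/mol).

    Accepts RNA or DNA alphabet (U is canonicalized to T internally); the
    structure string has the same length as the input and balanced
    brackets. Ambiguous bases (N) never pair. Deterministic: ties resolve
    toward the smallest closing-pair span and the leftmost stem.
    """
    if params is None:
        params = FoldParams(min_loop=min_loop, wobble=wobble)
    seq = canonical(sequence)
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = len(seq)
    table = _pair_energy_table(params.wobble)
    INF = math.inf

    E = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            e = table.get((seq[i], seq[j]))
            if e is not None:
                E[i, j] = e

    # V[i, j]: best energy of region i..j closed by pair (i, j)
    V = np.full((n, n), INF)
    choice: dict[tuple[int, int], tuple] = {}
    mb = params.max_bulge
    for span in range(params.min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not np.isfinite(E[i, j]):
                continue
            best = params.hairpin_penalty
            ch: tuple = ("hairpin",)
            # stacked continuation
            if j - i - 2 > params.min_loop and np.isfinite(V[i + 1, j - 1]):
                cand = V[i + 1, j - 1] + params.stack_bonus
                if cand < best:
                    best, ch = cand, ("stack",)
            # interior loop / bulge with at most mb unpaired bases
            for g1 in range(0, mb + 1):
                k = i + 1 + g1
                for g2 in range(0, mb + 1 - g1):
                    if g1 == 0 and g2 == 0:
                        continue
                    l = j - 1 - g2
                    if l - k <= params.min_loop:
                        break
                    if np.isfinite(V[k, l]):
                        cand = V[k, l] + params.bulge_penalty * (g1 + g2)
                        if cand < best:
                            best, ch = cand, ("interior", k, l)
            V[i, j] = E[i, j] + best
            choice[(i, j)] = ch

    # F[j]: best energy of the prefix of length j (stems side by side)
    F = np.zeros(n + 1)
    back: list[tuple | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        F[j] = F[j - 1]
        back[j] = ("unpaired",)
        for i in range(0, j - params.min_loop - 1):
            if np.isfinite(V[i, j - 1]):
                cand = F[i] + V[i, j - 1]
                if cand < F[j]:
                    F[j] = cand
                    back[j] = ("stem", i)
    mfe = float(F[n])

    structure = ["."] * n
    j = n
    stems: list[tuple[int, int]] = []
    while j > 0:
        step = back[j]
        if step[0] == "unpaired":
            j -= 1
        else:
            stems.append((step[1], j - 1))
            j = step[1]
    for i, j in stems:
        while True:
            structure[i] = "("
            structure[j] = ")"
            ch = choice[(i, j)]
            if ch[0] == "hairpin":
                break
            if ch[0] == "stack":
                i, j = i + 1, j - 1
            else:
                i, j = ch[1], ch[2]
    return "".join(structure), mfe


def structure_energy(
    seq: str, pairs: list[tuple[int, int]], params: FoldParams = DEFAULT_PARAMS
) -> float:
    """Energy of an explicit pair set under the bundled model.

    Returns ``inf`` for structures outside the engine's space (crossing
    pairs, multibranch loops, interior loops over the bulge budget, or
    loops below the minimum size). Used as the independent scoring route
    when cross-checking the fold.
    """
    seq = canonical(seq)
    table = _pair_energy_table(params.wobble)
    pairs = sorted(pairs)
    used = [b for p in pairs for b in p]
    if len(used) != len(set(used)):
        return math.inf  # a base in more than one pair
    energy = 0.0
    for i, j in pairs:
        e = table.get((seq[i], seq[j]))
        if e is None or j - i - 1 < params.min_loop:
            return math.inf
        energy += e
    for (i, j), (a, b) in zip(pairs, pairs[1:]):
        if i < a < j < b:  # crossing
            return math.inf
    for i, j in pairs:
        children = [
            (a, b) for a, b in pairs if i < a and b < j
            and not any(a2 < a and b < b2 for a2, b2 in pairs if i < a2 and b2 < j)
        ]
        if len(children) == 0:
            energy += params.hairpin_penalty
        elif len(children) == 1:
            (a, b) = children[0]
            gap = (a - i - 1) + (j - b - 1)
            if gap == 0:
                energy += params.stack_bonus
            elif gap <= params.max_bulge:
                energy += params.bulge_penalty * gap
            else:
                return math.inf
        else:
            return math.inf
    return energy


def pairs_from_structure(structure: str) -> list[tuple[int, int]]:
    """Decode a dot-bracket string into a sorted list of (i, j) pairs (0-based)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def gc_percent(sequence: str) -> float:
    """GC content on the 0-100 scale."""
    seq = canonical(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def duplex_energy(
    seq_a: str, seq_b: str, gap_penalty: float = 2.0, wobble: bool = True
) -> float:
    """Hybridization energy (kcal/mol, <= 0) of an intermolecular duplex.

    Both strands are given 5'->3'. The best (most negative) local duplex is
    found by dynamic programming over antiparallel pairings with a per-base
    gap penalty; G:U wobbles are admitted (hybridization is permissive even
    where the intramolecular default is strict). The value is symmetric in
    argument order, and 0 for strands with no complementarity.
    """
    a = canonical(seq_a)
    b = canonical(seq_b)[::-1]  # antiparallel
    if set(a + b) - set("ACGTN"):
        raise ValueError("non-nucleotide characters in duplex input")
    table = _pair_energy_table(wobble)
    n, m = len(a), len(b)
    INF = math.inf
    best = 0.0
    # D[i][j]: best energy of a duplex whose last pairing is a[i] with b[j]
    D = [[INF] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            e = table.get((a[i], b[j]))
            if e is None:
                continue
            prev = 0.0
            if i > 0 and j > 0:
                cand = [0.0, D[i - 1][j - 1]]
                for ii in range(i - 1):  # bulge on strand a
                    if D[ii][j - 1] < INF:
                        cand.append(D[ii][j - 1] + gap_penalty * (i - 1 - ii))
                for jj in range(j - 1):  # bulge on strand b
                    if D[i - 1][jj] < INF:
                        cand.append(D[i - 1][jj] + gap_penalty * (j - 1 - jj))
                prev = min(cand)
            D[i][j] = e + min(prev, 0.0)
            best = min(best, D[i][j])
    return best


# ---------------------------------------------------------------------------
# engine registry
# ---------------------------------------------------------------------------

def _vienna_fold(sequence: str, min_loop: int = MIN_LOOP, wobble: bool = True):
    import RNA  # lazy: optional thermodynamic engine

    structure, mfe = RNA.fold(canonical(sequence).replace("T", "U"))
    return structure, float(mfe)


def get_fold_engine(name: str = "builtin") -> Callable[..., tuple[str, float]]:
    """Return a fold callable by name: ``builtin`` (default) or ``vienna``."""
    if name == "builtin":
        return fold
    if name == "vienna":
        return _vienna_fold
    raise ValueError(f"unknown fold engine {name!r}")
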