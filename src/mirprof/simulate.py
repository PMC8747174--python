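"""Seeded synthetic sRNA-seq data with full ground truth.

The generator emulates the composition of a plant leaf small-RNA library:
a 21-24-nt-dominant insert length distribution, a 3' sequencing adapter
read into when inserts are short, conserved mature miRNAs planted at exact
copy numbers, hairpin precursors planted in a random genome (whose mature
arms seed the novel-discovery reads), ncRNA contaminant fragments
(rRNA/tRNA/snRNA/snoRNA), and random background noise. Planting is exact
by default (no sequencing-error model): the downstream pipeline operates
on collapsed exact tags, so each planted class is recoverable with zero
count error, and every read's class and source are recorded in a truth
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mirprof.cleaning import NCRNA_CLASS_ORDER
from mirprof.seqio import ReferenceMatureRecord, SmallRNARead, canonical, reverse_complement

#: default 3' adapter (Illumina TruSeq small-RNA)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: default insert length distribution: dominant 24 nt, strong 21-23 nt,
#: thin 16-40 nt tails (mirrors a typical plant sRNA library)
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    **{n: 0.01 for n in range(16, 21)},
    21: 0.15,
    22: 0.15,
    23: 0.12,
    24: 0.35,
    **{n: 0.18 / 16 for n in range(25, 41)},
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class HairpinDesign:
    """Blueprint for a planted stem-loop precursor.

    The precursor is mature + loop + near-reverse-complement star (5p arm)
    or star + loop + mature (3p arm); ``stem_mismatches`` substitutions are
    scattered on the star arm. With <= 2 mismatches the construct folds
    into a single stem-loop satisfying the discovery criteria.
    """

    mature: str
    arm: str  # '5p' | '3p'
    loop_length: int
    stem_mismatches: int = 0
    genome_position: tuple[str, int, str] = ("chr1", 0, "+")  # contig, start, strand

    def __post_init__(self) -> None:
        if not (20 <= len(self.mature) <= 24):
            raise ValueError("mature length must be 20-24 nt")
        if self.arm not in ("5p", "3p"):
            raise ValueError("arm must be '5p' or '3p'")
        if self.loop_length < 3:
            raise ValueError("loop must be >= 3 nt")
        if self.stem_mismatches < 0 or self.stem_mismatches >= len(self.mature) / 4:
            raise ValueError("stem mismatches must be < mature length / 4")

    @property
    def precursor_length(self) -> int:
        return 2 * len(self.mature) + self.loop_length


@dataclass
class SimulationConfig:
    """Composition of a synthetic library (exact planted counts)."""

    seed: int
    n_reads: int
    adapter: str = DEFAULT_ADAPTER
    planted_conserved: list[tuple[ReferenceMatureRecord, int]] = field(default_factory=list)
    planted_hairpins: list[tuple[HairpinDesign, int]] = field(default_factory=list)
    contaminant_fraction: float = 0.0
    noise_fraction: float = 0.0
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    read_length: int = 50
    quality: int = 40

    def validate(self) -> None:
        if not (0 <= self.contaminant_fraction <= 1 and 0 <= self.noise_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        planted = sum(c for _, c in self.planted_conserved) + sum(
            c for _, c in self.planted_hairpins
        )
        if any(c < 1 for _, c in self.planted_conserved + self.planted_hairpins):
            raise ValueError("copy numbers must be >= 1")
        budget = planted / self.n_reads + self.contaminant_fraction + self.noise_fraction
        if budget > 1 + 1e-9:
            raise ValueError(
                f"planted + contaminant + noise proportions exceed 1 ({budget:.3f})"
            )
        if any(length < 16 or length > 40 for length in self.length_distribution):
            raise ValueError("length distribution must cover 16-40 nt only")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_hairpin_precursor(design: HairpinDesign, rng_seed: int) -> str:
    """Construct the precursor sequence for a design (deterministic per seed).

    The star arm is the reverse complement of the mature with
    ``stem_mismatches`` substitutions at seeded random positions; the loop
    is random sequence of the designed length.
    """
    rng = np.random.default_rng(rng_seed)
    mature = canonical(design.mature)
    star = list(reverse_complement(mature))
    if design.stem_mismatches:
        positions = rng.choice(len(star), size=design.stem_mismatches, replace=False)
        for pos in positions:
            star[pos] = str(rng.choice(_BASES[_BASES != star[pos]]))
    loop = _random_seq(rng, design.loop_length)
    star_seq = "".join(star)
    if design.arm == "5p":
        return mature + loop + star_seq
    return star_seq + loop + mature


def build_genome(
    designs: Sequence[HairpinDesign],
    contig_length: int,
    seed: int,
    contig_name: str = "chr1",
) -> dict[str, str]:
    """Random background genome with precursors inserted at their coordinates.

    Backgrounds use symmetric base probabilities (expected GC 50%).
    Precursors are written onto the forward strand, reverse complemented
    first for '-' strand designs, so the excised window always contains the
    designed stem-loop. Overlapping or out-of-bounds insertions are errors.
    """
    rng = np.random.default_rng(seed)
    contig = list(_random_seq(rng, contig_length))
    intervals: list[tuple[int, int]] = []
    for k, design in enumerate(designs):
        contig_id, start, strand = design.genome_position
        if contig_id != contig_name:
            raise ValueError(f"design contig {contig_id!r} != {contig_name!r}")
        pre = make_hairpin_precursor(design, rng_seed=seed + 101 * k)
        end = start + len(pre)
        if start < 0 or end > contig_length:
            raise ValueError(f"precursor at {start}-{end} outside contig bounds")
        for a, b in intervals:
            if start < b and a < end:
                raise ValueError("planted precursor intervals overlap")
        intervals.append((start, end))
        inserted = pre if strand == "+" else reverse_complement(pre)
        contig[start:end] = list(inserted)
    return {contig_name: "".join(contig)}


def _sample_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[length] for length in lengths], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def make_contaminant_set(
    seed: int, lengths: Optional[dict[str, int]] = None
) -> list[tuple[str, str, str]]:
    """Random ncRNA contaminant records, one per class, as (class, id, seq)."""
    if lengths is None:
        lengths = {"rRNA": 1500, "tRNA": 76, "snRNA": 150, "snoRNA": 120}
    rng = np.random.default_rng(seed)
    return [
        (cls, f"{cls}_1", _random_seq(rng, lengths[cls]))
        for cls in NCRNA_CLASS_ORDER
        if cls in lengths
    ]


def simulate_library(
    cfg: SimulationConfig,
    contaminants: Optional[Sequence[tuple[str, str, str]]] = None,
) -> tuple[list[SmallRNARead], pd.DataFrame]:
    """Simulate a library; returns (reads, truth table).

    Each read is insert + adapter truncated to ``read_length``, with
    uniform quality. The truth table has one row per read: read_id, class
    (``conserved:<ref_id>``, ``hairpin:<contig>:<start>:<arm>``,
    ``contaminant:<class>``, ``noise``), source_id, insert sequence and
    genome_position. Counts match the config exactly for planted classes;
    byte-identical output for identical configs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if contaminants is None and cfg.contaminant_fraction > 0:
        contaminants = make_contaminant_set(cfg.seed + 7)

    inserts: list[tuple[str, str, str, str]] = []  # class, source_id, insert, position
    for record, copies in cfg.planted_conserved:
        for _ in range(copies):
            inserts.append(
                (f"conserved:{record.ref_id}", record.ref_id, canonical(record.sequence), "")
            )
    for design, copies in cfg.planted_hairpins:
        contig, start, strand = design.genome_position
        cls = f"hairpin:{contig}:{start}:{design.arm}"
        for _ in range(copies):
            inserts.append(
                (cls, f"{contig}:{start}", canonical(design.mature), f"{contig}:{start}:{strand}")
            )
    n_planted = len(inserts)
    n_contaminant = int(round(cfg.contaminant_fraction * cfg.n_reads))
    n_noise = cfg.n_reads - n_planted - n_contaminant
    if n_noise < 0:
        raise ValueError("planted reads exceed n_reads after contaminant allocation")

    for _ in range(n_contaminant):
        cls, rec_id, seq = contaminants[int(rng.integers(len(contaminants)))]
        length = min(_sample_length(rng, cfg.length_distribution), len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        inserts.append((f"contaminant:{cls}", rec_id, canonical(seq[start : start + length]), ""))
    for _ in range(n_noise):
        length = _sample_length(rng, cfg.length_distribution)
        inserts.append(("noise", "random", _random_seq(rng, length), ""))

    order = rng.permutation(len(inserts))
    reads: list[SmallRNARead] = []
    truth_rows = []
    for i, idx in enumerate(order):
        cls, source, insert, position = inserts[idx]
        read_id = f"read{i + 1}"
        seq = (insert + canonical(cfg.adapter))[: cfg.read_length]
        reads.append(SmallRNARead(read_id, seq, [cfg.quality] * len(seq)))
        truth_rows.append(
            {
                "read_id": read_id,
                "class": cls,
                "source_id": source,
                "insert": insert,
                "genome_position": position,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "class", "source_id", "insert", "genome_position"]
    )
    return reads, truth


def make_reference_set(
    n: int, seed: int, length_range: tuple[int, int] = (20, 22), prefix: str = "ath"
) -> list[ReferenceMatureRecord]:
    """Random mature reference records for simulations and tests."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        records.append(
            ReferenceMatureRecord(
                ref_id=f"{prefix}-miR{9000 + i}",
                family=f"MIR{9000 + i}",
                sequence=_random_seq(rng, length),
            )
        )
    return records
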