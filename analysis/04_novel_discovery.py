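#!/usr/bin/env python
"""Call novel miRNAs from the unassigned tags: map to the synthetic
genome, excise and fold precursor windows, apply the stem-loop screen,
gate on MFEI >= 0.70 and copy number >= 5, and verify the calls against
the planted truth.
"""

from pathlib import Path

import pandas as pd

from mirprof import seqio
from mirprof.cleaning import tags_from_fasta
from mirprof.novel import discover_novel, write_structures

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tags = tags_from_fasta(ROOT / "unassigned.fa")
    genome = seqio.read_fasta_genome(ROOT / "study" / "genome.fa")
    calls, candidates = discover_novel(tags, genome)
    calls.to_csv(ROOT / "novel_calls.tsv", sep="\t", index=False)
    write_structures([c for c in candidates if c.passed], ROOT / "precursors.vienna")

    print(f"{len(candidates)} candidate windows folded; {len(calls)} novel calls:")
    print(calls[["name", "sequence", "length_nt", "read_count", "strand", "mfei"]]
          .to_string(index=False))

    truth = pd.read_csv(ROOT / "study" / "truth.tsv", sep="\t")
    hairpin_reads = truth[truth["class"].str.startswith("hairpin:")]
    planted = set(hairpin_reads["insert"])
    called = set(calls["sequence"])
    print(f"\nplanted matures recovered: {len(planted & called)}/{len(planted)}")


if __name__ == "__main__":
    main()
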