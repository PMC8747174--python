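#!/usr/bin/env python
"""Build the synthetic study: genome with planted hairpins, mature
reference set, contaminant set, and a 10k-read sRNA library with truth.

Writes the study inputs under results/study/ so the later steps (and any
external tool) can consume them as plain FASTA/FASTQ/TSV.
"""

from pathlib import Path

from mirprof import seqio
from mirprof.pipeline import make_study_bundle

SEED = 20240901 % (2**31 - 1)
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = make_study_bundle(seed=SEED, n_reads=10_000, genome_length=50_000,
                               n_conserved=10, n_hairpins=3)
    seqio.write_sequences(bundle["reads"], OUT / "reads.fastq")
    bundle["truth"].to_csv(OUT / "truth.tsv", sep="\t", index=False)
    seqio.write_fasta_genome(bundle["genome"], OUT / "genome.fa")
    seqio.write_reference_set(bundle["reference"], OUT / "reference.fa")
    with open(OUT / "contaminants.fa", "w") as fh:
        for cls, rec_id, seq in bundle["contaminants"]:
            fh.write(f">{rec_id}|{cls}\n{seq}\n")

    counts = bundle["truth"]["class"].str.split(":").str[0].value_counts()
    print(f"simulated {len(bundle['reads'])} reads (seed {SEED}):")
    print(counts.to_string())
    print(f"planted hairpins: {[(d.arm, d.genome_position) for d in bundle['designs']]}")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
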