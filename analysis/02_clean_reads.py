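#!/usr/bin/env python
"""Clean the simulated library: trim the 3' adapter, drop low-quality and
out-of-range reads, collapse to unique tags, remove ncRNA contaminants.

Reports the read-categorization table and the tag length distribution
(the library is built 24-nt-dominant; the distribution argmax checks it).
"""

from pathlib import Path

from mirprof import cleaning, seqio
from mirprof.simulate import DEFAULT_ADAPTER

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    reads = seqio.read_sequences(ROOT / "study" / "reads.fastq")
    contaminants = []
    for rec in seqio.read_sequences(ROOT / "study" / "contaminants.fa", format="fasta"):
        rec_id, cls = rec.read_id.split("|")
        contaminants.append((cls, rec_id, rec.sequence))

    tags, report = cleaning.clean_reads(reads, adapter=DEFAULT_ADAPTER,
                                        contaminants=contaminants)
    report.check_conservation()
    cleaning.tags_to_fasta(tags, ROOT / "tags.fa")
    report.to_frame().to_csv(ROOT / "cleaning_report.tsv", sep="\t", index=False)
    dist = cleaning.length_distribution(tags)
    dist.to_csv(ROOT / "length_distribution.tsv", sep="\t", index=False)

    print(report.to_frame().to_string(index=False))
    top = dist.loc[dist["tag_count"].idxmax()]
    print(f"most abundant tag length: {int(top['length'])} nt ({top['percent']:.2f}% of unique tags)")


if __name__ == "__main__":
    main()
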