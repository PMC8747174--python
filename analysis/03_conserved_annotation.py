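#!/usr/bin/env python
"""Classify cleaned tags against the mature reference set and summarize
families; also recompute the family statistics of the packaged
M. koenigii conserved-miRNA table.
"""

from pathlib import Path

from mirprof import cleaning, seqio
from mirprof.conserved import assignments_to_frame, classify_conserved, summarize_families

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tags = cleaning.tags_from_fasta(ROOT / "tags.fa")
    refs = seqio.read_reference_set(ROOT / "study" / "reference.fa")
    assignments, unassigned = classify_conserved(tags, refs, max_mismatch=1)
    table = assignments_to_frame(assignments)
    table.to_csv(ROOT / "conserved_assignments.tsv", sep="\t", index=False)
    cleaning.tags_to_fasta(unassigned, ROOT / "unassigned.fa")
    print(f"{len(assignments)} tags assigned to {table['reference_mirna'].nunique()} "
          f"reference miRNAs; {len(unassigned)} tags left for novel discovery")

    fixture = seqio.load_table2_fixture()
    fams = summarize_families(fixture)
    fams.to_csv(ROOT / "fixture_family_summary.tsv", sep="\t", index=False)
    named = fams[fams["family"] != "NA"]
    print(f"\npackaged conserved table: {len(fixture)} miRNAs in {len(named)} named families")
    print("top families by reads:")
    print(named.head(4).to_string(index=False))


if __name__ == "__main__":
    main()
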