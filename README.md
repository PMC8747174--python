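# mirprof

Small-RNA miRNA profiling for plants: a tested re-implementation of the
classic sRNA-seq discovery workflow used to characterize the miRNA
repertoire of the curry-leaf tree *Murraya koenigii*, with packaged
reference tables (142 conserved miRNAs in 34 families; 7 novel
candidates) and a seeded synthetic-data generator so that every stage can
be validated against known ground truth.

The pipeline covers:

1. **Read cleaning** — 3′ adapter trimming, mean-Phred < Q30 removal,
   16–40 nt length filter, collapsing to unique tags, and removal of
   rRNA/tRNA/snRNA/snoRNA contaminants by substring match on both strands.
2. **Conserved annotation** — ungapped homology of each tag to a mature
   miRNA reference set with at most one substitution (shorter sequence
   contained in the longer, overhangs free), family assignment and
   family summaries.
3. **Novel discovery** — mapping unassigned tags to a genome, excising
   candidate precursor windows, folding them, screening for a single
   stem-loop with the mature on one arm, and gating on the minimal
   folding free energy index

   AMFE = (|MFE| / L) × 100,  MFEI = AMFE / GC%

   with MFEI ≥ 0.70 and read count (copy number) ≥ 5.
4. **Target prediction** — plant-mode expectation scoring (mismatch 1.0,
   G:U wobble 0.5, doubled over miRNA positions 2–13, expectation ≤ 5)
   with cleavage vs translational-repression calling from central
   (positions 9–11) complementarity; cross-kingdom mode with a strict
   Watson–Crick seed (positions 2–8) and duplex energy |ΔG| ≥ 25
   kcal/mol; MFE-weighted edge-list export for network tools.
5. **qPCR quantification** — 2^−ΔΔCt relative expression with a U6-style
   endogenous control and a miR156a-5p calibrator, replicate summaries,
   and ANOVA + Tukey HSD compact letter groups.

The fold engine is a bundled dynamic program over simple stem-loops
(stack bonus, hairpin-loop and bulge penalties); ViennaRNA can be
substituted via configuration where thermodynamic energies are wanted.

## Worked example

Summarize the packaged *M. koenigii* reference tables:

```bash
mirprof report
```

```json
{
  "conserved_mirnas": 142,
  "conserved_families": 34,
  "novel_mirnas": 7,
  "novel_mfei_mean": 0.85,
  "top_family": "MIR166"
}
```

142 conserved miRNAs fall into 34 named families; MIR166 is the largest
(16 members, 2795 reads), followed by MIR396 (1598 reads) and MIR159
(1364). The seven novel candidates carry precursor MFEI values from 0.70
to 0.98 (mean 0.85), above the ~0.70 level that separates miRNA
precursors from tRNA/rRNA/mRNA background, with read counts from 5 to 93
(top candidate mko-miRN7-3p, 93 reads).

The numbered scripts under `analysis/` run the same pipeline end to end
on a synthetic 10,000-read library with planted ground truth:

```bash
python analysis/01_simulate_library.py
python analysis/02_clean_reads.py
python analysis/03_conserved_annotation.py
python analysis/04_novel_discovery.py
python analysis/05_target_prediction.py
python analysis/06_qpcr_expression.py
```

On the default seed the cleaning report balances exactly (10,000 reads in,
9,000 surviving after 1,000 contaminant reads are removed by class), the
unique-tag length distribution peaks at 24 nt, all ten planted conserved
miRNAs are recovered with zero count error, and all three planted
hairpins are called:

```
        name                sequence  length_nt  read_count strand  mfei
mko-miRN1-5p  GCTCTGCGTGGTAGATCTAAGT         22          60      -  2.21
mko-miRN2-3p  ACCGAGCTTGACCTTGGACCTT         22          55      -  2.09
mko-miRN3-5p CCCGTCAGCAAGGACAGTTTGTT         23          45      +  1.78
planted matures recovered: 3/3
```

The qPCR step recovers known fold changes within 6.6% under 0.1-cycle Ct
noise and separates the planted expression levels into distinct Tukey
letter groups.

Each stage is also exposed as a CLI subcommand (`mirprof simulate`,
`clean`, `conserved`, `novel`, `targets`, `qpcr`, `report`); see
`mirprof --help`.

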