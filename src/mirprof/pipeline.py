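"""End-to-end pipeline drivers over synthetic studies.

``make_study_bundle`` builds a coherent synthetic experiment (genome with
planted hairpins, mature reference set, sequencing library with truth
table); ``run_pipeline`` executes cleaning, conserved annotation and novel
discovery on it and returns everything needed to score recovery against
the truth.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from mirprof import cleaning, conserved, novel, simulate
from mirprof.seqio import canonical


def make_study_bundle(
    seed: int,
    n_reads: int = 10000,
    contaminant_fraction: float = 0.1,
    noise_fraction: float = 0.5,
    n_conserved: int = 10,
    n_hairpins: int = 3,
    genome_length: int = 50000,
    conserved_copies: tuple[int, int] = (5, 60),
    hairpin_copies: tuple[int, int] = (5, 95),
    max_stem_mismatches: int = 2,
) -> dict:
    """Build a coherent synthetic study: genome, reference, library, truth.

    Copy-number ranges default to the span observed for real candidate
    miRNAs at desk scale (5-95 reads). Hairpin designs alternate arms and
    strands and carry up to ``max_stem_mismatches`` star-arm substitutions.
    """
    rng = np.random.default_rng(seed)
    reference = simulate.make_reference_set(n_conserved, seed=seed + 1)
    planted_conserved = [
        (rec, int(rng.integers(conserved_copies[0], conserved_copies[1] + 1)))
        for rec in reference
    ]
    designs = []
    pos = 2000
    for k in range(n_hairpins):
        mature_len = int(rng.integers(21, 24))
        mature = "".join(rng.choice(list("ACGT"), size=mature_len))
        designs.append(
            simulate.HairpinDesign(
                mature=mature,
                arm="5p" if k % 2 == 0 else "3p",
                loop_length=int(rng.integers(8, 16)),
                stem_mismatches=int(rng.integers(0, max_stem_mismatches + 1)),
                genome_position=("chr1", pos, "+" if k % 2 == 0 else "-"),
            )
        )
        pos += int(rng.integers(3000, 6000))
    genome = simulate.build_genome(designs, genome_length, seed=seed + 2)
    planted_hairpins = [
        (d, int(rng.integers(hairpin_copies[0], hairpin_copies[1] + 1))) for d in designs
    ]
    cfg = simulate.SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        planted_conserved=planted_conserved,
        planted_hairpins=planted_hairpins,
        contaminant_fraction=contaminant_fraction,
        noise_fraction=noise_fraction,
    )
    contaminants = simulate.make_contaminant_set(seed + 7)
    reads, truth = simulate.simulate_library(cfg, contaminants=contaminants)
    return {
        "reads": reads,
        "truth": truth,
        "genome": genome,
        "reference": reference,
        "contaminants": contaminants,
        "config": cfg,
        "designs": designs,
        "planted_conserved": planted_conserved,
        "planted_hairpins": planted_hairpins,
    }


def run_pipeline(
    bundle: dict,
    max_mismatch_conserved: int = 1,
    max_mismatch_genome: int = 0,
    flank: int = 150,
    mfei_threshold: float = 0.70,
    copy_threshold: int = 5,
) -> dict:
    """Clean, annotate and discover on a synthetic study bundle."""
    cfg = bundle["config"]
    tags, report = cleaning.clean_reads(
        bundle["reads"],
        adapter=cfg.adapter,
        contaminants=bundle["contaminants"],
    )
    assignments, unassigned = conserved.classify_conserved(
        tags, bundle["reference"], max_mismatch=max_mismatch_conserved
    )
    calls, candidates = novel.discover_novel(
        unassigned,
        bundle["genome"],
        max_mismatch=max_mismatch_genome,
        flank=flank,
        mfei_threshold=mfei_threshold,
        copy_threshold=copy_threshold,
    )
    return {
        "tags": tags,
        "report": report,
        "assignments": assignments,
        "unassigned": unassigned,
        "novel_calls": calls,
        "candidates": candidates,
    }


def score_conserved_recovery(bundle: dict, assignments) -> dict[str, float]:
    """Recall/precision and count error of conserved assignment vs truth."""
    truth_counts = (
        bundle["truth"]["class"]
        .loc[bundle["truth"]["class"].str.startswith("conserved:")]
        .str.removeprefix("conserved:")
        .value_counts()
        .to_dict()
    )
    assigned = {a.ref_id: a.read_count for a in assignments}
    planted = set(truth_counts)
    recovered = set(assigned)
    tp = len(planted & recovered)
    recall = tp / len(planted) if planted else 1.0
    precision = tp / len(recovered) if recovered else 1.0
    count_err = sum(
        abs(assigned.get(ref, 0) - n) for ref, n in truth_counts.items()
    )
    return {"recall": recall, "precision": precision, "total_count_error": count_err}


def score_novel_recovery(bundle: dict, calls: pd.DataFrame) -> dict[str, float]:
    """Sensitivity of novel calling against the planted hairpin designs."""
    planted = {canonical(d.mature) for d, _ in bundle["planted_hairpins"]}
    called = set(calls["sequence"]) if len(calls) else set()
    tp = len(planted & called)
    return {
        "sensitivity": tp / len(planted) if planted else 1.0,
        "n_calls": float(len(called)),
        "false_calls": float(len(called - planted)),
    }
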