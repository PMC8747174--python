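"""Target prediction: expectation scoring, mode calling, seed/energy gates."""

import random

import pytest

from mirprof.seqio import reverse_complement
from mirprof.targets import (
    MATCH,
    PenaltyScheme,
    TargetHit,
    _align_codes,
    call_mode,
    cross_kingdom_scan,
    expectation_score,
    export_network,
    hits_to_frame,
    mode_fractions,
    plant_target_scan,
)

MIRNA = "TTGACAGAAGAGAGTGAGCAC"  # 21 nt


def perfect_site(mirna):
    return reverse_complement(mirna)


def site_with_change(mirna, pos_1based, kind):
    """Build a target site imperfect at a given miRNA position.

    kind 'mismatch' makes the target base equal the miRNA base (never
    pairs); 'wobble' builds a G:U (only valid where the miRNA base is G or
    T).
    """
    site = list(perfect_site(mirna))
    idx = len(mirna) - pos_1based  # site index facing miRNA position
    base = mirna[pos_1based - 1]
    if kind == "mismatch":
        site[idx] = base
    else:
        site[idx] = {"G": "T", "T": "G"}[base]
    return "".join(site)


def brute_best_window(mirna, transcript, scheme=PenaltyScheme()):
    """Exhaustive window-enumeration oracle (independent of the scanner)."""
    L = len(mirna)
    best = None
    for start in range(len(transcript) - L + 1):
        aln = _align_codes(mirna, transcript[start : start + L])
        exp = expectation_score(aln, scheme)
        if best is None or exp < best[0]:
            best = (exp, start)
    return best


class TestExpectation:
    def test_perfect_complement_scores_zero(self):
        hits = plant_target_scan(MIRNA, {"t1": "AAA" + perfect_site(MIRNA) + "GGG"})
        assert len(hits) == 1
        assert hits[0].expectation == 0.0
        assert hits[0].target_start == 4

    def test_single_wobble_outside_seed(self):
        site = site_with_change(MIRNA, 16, "wobble")  # position 16 is a G
        hits = plant_target_scan(MIRNA, {"t": site})
        assert hits[0].expectation == pytest.approx(0.5)

    def test_seed_mismatch_doubled(self):
        site = site_with_change(MIRNA, 5, "mismatch")
        hits = plant_target_scan(MIRNA, {"t": site})
        assert hits[0].expectation == pytest.approx(2.0)

    def test_seed_wobble_doubled(self):
        site = site_with_change(MIRNA, 3, "wobble")
        hits = plant_target_scan(MIRNA, {"t": site})
        assert hits[0].expectation == pytest.approx(1.0)

    def test_agrees_with_bruteforce_window_enumeration(self):
        rng = random.Random(31)
        transcript = "".join(rng.choice("ACGT") for _ in range(500))
        # plant a decent site
        transcript = transcript[:200] + site_with_change(MIRNA, 5, "mismatch") + transcript[221:]
        hits = plant_target_scan(MIRNA, {"t": transcript}, expectation_cutoff=1e9)
        exp, start = brute_best_window(MIRNA, transcript)
        assert hits[0].expectation == pytest.approx(exp)
        assert hits[0].target_start == start + 1

    def test_cutoff_monotonicity(self):
        rng = random.Random(13)
        transcripts = {
            f"t{i}": "".join(rng.choice("ACGT") for _ in range(300)) for i in range(20)
        }
        strict = {h.transcript_id for h in plant_target_scan(MIRNA, transcripts, 3.0)}
        loose = {h.transcript_id for h in plant_target_scan(MIRNA, transcripts, 5.0)}
        assert strict <= loose

    def test_mirna_length_validated(self):
        with pytest.raises(ValueError):
            plant_target_scan("ACGT", {"t": "ACGTACGT"})


class TestModeCall:
    def _hit(self, alignment):
        return TargetHit("m", "t", alignment, 0.0, None, None, 1, len(alignment))

    def test_perfect_complement_is_cleavage(self):
        hits = plant_target_scan(MIRNA, {"t": perfect_site(MIRNA)})
        assert hits[0].mode == "cleavage"

    def test_central_mismatch_is_translation(self):
        site = site_with_change(MIRNA, 10, "mismatch")
        hits = plant_target_scan(MIRNA, {"t": site})
        assert hits[0].mode == "translation"

    @pytest.mark.parametrize("pos", [9, 10, 11])
    def test_any_central_imperfection_triggers_translation(self, pos):
        aln = [MATCH] * 21
        aln[pos - 1] = "."
        assert call_mode(self._hit("".join(aln))) == "translation"

    def test_constructed_truth_recovered_completely(self):
        rng = random.Random(41)
        transcripts, expected = {}, {}
        for i in range(30):
            if i % 2:
                site = site_with_change(MIRNA, rng.choice([9, 10, 11]), "mismatch")
                expected[f"t{i}"] = "translation"
            else:
                site = site_with_change(MIRNA, rng.choice([1, 15, 18]), "mismatch")
                expected[f"t{i}"] = "cleavage"
            pad = "".join(rng.choice("ACGT") for _ in range(50))
            transcripts[f"t{i}"] = pad + site + pad
        hits = plant_target_scan(MIRNA, transcripts)
        assert {h.transcript_id: h.mode for h in hits} == expected
        fracs = mode_fractions(hits)
        assert fracs["cleavage"] + fracs["translation"] == pytest.approx(1.0)


class TestCrossKingdom:
    STRONG_MIRNA = "TGAGGCCGCGGCAGGCCGAGGC"  # GC-rich so a full site is strong

    def test_perfect_seed_strong_pairing_emitted(self):
        site = perfect_site(self.STRONG_MIRNA)
        hits = cross_kingdom_scan(self.STRONG_MIRNA, {"t": "AA" + site + "AA"})
        assert len(hits) == 1
        assert hits[0].duplex_energy < -25

    def test_weak_overall_pairing_rejected(self):
        # perfect seed (positions 2-8) but nothing else pairs
        mirna = self.STRONG_MIRNA
        site = list("A" * len(mirna))
        L = len(mirna)
        perfect = perfect_site(mirna)
        for k in range(2, 9):
            site[L - k] = perfect[L - k]
        hits = cross_kingdom_scan(mirna, {"t": "".join(site)})
        assert hits == []

    def test_seed_wobble_rejected_regardless_of_energy(self):
        mirna = self.STRONG_MIRNA
        site = list(perfect_site(mirna))
        # make position 5 a G:U wobble (miRNA G faces T)
        k = 5
        assert mirna[k - 1] == "G"
        site[len(mirna) - k] = "T"
        hits = cross_kingdom_scan(mirna, {"t": "".join(site)})
        assert hits == []

    def test_literal_energy_rule_admits_weak_duplexes(self):
        mirna = self.STRONG_MIRNA
        site = list("A" * len(mirna))
        L = len(mirna)
        perfect = perfect_site(mirna)
        for k in range(2, 9):
            site[L - k] = perfect[L - k]
        hits = cross_kingdom_scan(
            mirna, {"t": "".join(site)}, literal_energy_rule=True
        )
        assert len(hits) == 1  # weak duplex admitted under the literal reading


class TestNetworkExport:
    def _hits(self):
        return [
            TargetHit("m1", "t1", "|" * 21, 0.0, -30.0, "cleavage", 1, 21),
            TargetHit("m1", "t2", "|" * 21, 1.0, -10.0, "translation", 1, 21),
            TargetHit("m2", "t3", "|" * 21, 2.0, -20.0, "cleavage", 1, 21),
        ]

    def test_one_edge_per_hit(self, tmp_path):
        df = export_network(self._hits(), tmp_path / "net.tsv")
        assert len(df) == 3

    def test_weak_flag_rule(self, tmp_path):
        df = export_network(self._hits(), tmp_path / "net.tsv", weak_cutoff=-15.0)
        flags = dict(zip(df["target"], df["weak_flag"]))
        assert flags == {"t1": False, "t2": True, "t3": False}

    def test_empty_hit_set_writes_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        export_network([], path)
        assert path.read_text().splitlines() == ["source\ttarget\tweight\tweak_flag"]

    def test_deterministic_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_network(self._hits(), p1)
        export_network(self._hits(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_hits_frame_partition_exhaustive(self):
        df = hits_to_frame(self._hits())
        assert set(df["mode"]) <= {"cleavage", "translation"}
        assert df["mode"].notna().all()
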