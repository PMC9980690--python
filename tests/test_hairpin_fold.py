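"""Folding stage: linker location, strand realignment, dyad calls, UMI dedup."""

import random

import numpy as np
import pytest

from hairpinrcp import hairpin_fold as hf
from hairpinrcp import synthetic_data as sd

LINKER = sd.DEFAULT_LINKER


def _clean_reads(reference, spec):
    mols = sd.simulate_molecules(spec)
    reads = sd.emit_hairpin_reads(mols, spec, *reference)
    truth = {
        (m.individual_id, m.umi): m.collapsed_states()
        for v in mols.values()
        for m in v
    }
    return reads, truth


class TestFindLinker:
    def test_exact_read_locates_emission_position(self, reference, clean_spec):
        ref, cpg = reference
        reads, _ = _clean_reads(reference, clean_spec)
        for read_id, seq in reads[:5]:
            span, umi, *_ = hf.find_linker(seq, LINKER)
            assert span == (len(ref), len(ref) + len(LINKER))
            assert len(umi) == clean_spec.umi_length

    def test_fully_converted_linker_still_matches(self):
        umi = "GATTAGGT"
        converted = LINKER.replace("N" * 8, umi).replace("C", "T")
        read = "A" * 30 + converted + "A" * 30
        hit = hf.find_linker(read, LINKER, max_mismatch=0)
        assert hit is not None
        span, found_umi, ctrl_total, ctrl_unconv = hit
        assert span == (30, 30 + len(LINKER))
        assert found_umi == umi
        # every template C was seen converted
        assert ctrl_total == LINKER.count("C") and ctrl_unconv == 0

    def test_retained_linker_cytosines_counted_as_controls(self):
        umi = "GATTAGGT"
        read = "A" * 20 + LINKER.replace("N" * 8, umi) + "A" * 20  # no conversion
        _, _, ctrl_total, ctrl_unconv = hf.find_linker(read, LINKER)
        assert ctrl_total == ctrl_unconv == LINKER.count("C")

    def test_random_reads_rarely_match(self):
        """False-positive rate below 1% on 1,000 random reads."""
        rng = np.random.default_rng(0)
        hits = sum(
            hf.find_linker("".join(rng.choice(list("ACGT"), size=150)), LINKER)
            is not None
            for _ in range(1000)
        )
        assert hits < 10


class TestFoldAndAlign:
    def test_error_free_read_aligns_gapless_and_concordant(self, reference, clean_spec):
        reads, _ = _clean_reads(reference, clean_spec)
        for read_id, seq in reads[:5]:
            span, umi, *_ = hf.find_linker(seq, LINKER)
            aln = hf.fold_and_align(hf.HairpinRead(read_id, seq, span, umi))
            assert all(a != "-" and b != "-" for a, b in aln.aligned_columns)
            assert aln.identity == 1.0

    def test_single_insertion_in_bottom_arm_gives_one_gap(self, reference, clean_spec):
        ref, cpg = reference
        reads, truth = _clean_reads(reference, clean_spec)
        read_id, seq = reads[0]
        span = (len(ref), len(ref) + len(LINKER))
        # insert 1 nt into the bottom arm between CpG complement positions
        cut = span[1] + 40
        mutated = seq[:cut] + "G" + seq[cut:]
        hit = hf.find_linker(mutated, LINKER)
        aln = hf.fold_and_align(hf.HairpinRead(read_id, mutated, hit[0], hit[1]))
        n_gap_cols = sum(1 for a, b in aln.aligned_columns if a == "-" or b == "-")
        assert n_gap_cols == 1
        states = hf.call_dyads(aln, ref, cpg)
        ind, _ = read_id.split("|")
        assert states == truth[(ind, hit[1])]

    def test_short_arm_discarded(self, reference, clean_spec):
        reads, _ = _clean_reads(reference, clean_spec)
        read_id, seq = reads[0]
        truncated = seq[90:]  # destroys most of the top arm
        hit = hf.find_linker(truncated, LINKER)
        with pytest.raises(ValueError, match="arm below minimum"):
            hf.fold_and_align(hf.HairpinRead(read_id, truncated, hit[0], hit[1]))

    def test_shuffled_arms_fall_below_identity_threshold(self, reference):
        """Arms of unrelated sequence score as chimeras (identity < 0.8)."""
        ref, cpg = reference
        spec = sd.SimSpec(n_individuals_per_group=1, molecules_per_individual=30,
                          seed=21)
        reads, _ = _clean_reads(reference, spec)
        rng = random.Random(0)
        config = hf.FoldConfig()
        identities = []
        for read_id, seq in reads:
            span, umi, *_ = hf.find_linker(seq, LINKER)
            right = list(seq[span[1]:])
            rng.shuffle(right)
            shuffled = seq[: span[1]] + "".join(right)
            aln = hf.fold_and_align(hf.HairpinRead(read_id, shuffled, span, umi))
            identities.append(aln.identity)
        assert max(identities) < config.min_identity


class TestCallDyads:
    def test_all_dyad_classes_recovered(self, reference):
        """M, U, and both hemimethylation orientations classify correctly."""
        ref, cpg = reference
        spec = sd.SimSpec(n_individuals_per_group=1, molecules_per_individual=1,
                          fail_rate=0.0, inappropriate_rate=0.0, seed=1)
        mol = sd.TrueMolecule("ind01", ("M", "U", "Ht", "Hb", "M"), "GATTAGGT")
        (read_id, seq), = sd.emit_hairpin_reads({"ind01": [mol]}, spec, ref, cpg)
        span, umi, *_ = hf.find_linker(seq, LINKER)
        aln = hf.fold_and_align(hf.HairpinRead(read_id, seq, span, umi))
        assert hf.call_dyads(aln, ref, cpg) == ("M", "U", "H", "H", "M")


class TestDedupUmi:
    def _rec(self, states, umi="AAGGTTAA", sample="s1", ctrl=(5, 0)):
        return hf.MoleculeRecord(sample, umi, tuple(states), *ctrl)

    def test_identical_duplicates_collapse(self):
        recs = [self._rec("MUHMU"), self._rec("MUHMU")]
        out = hf.dedup_umi(recs)
        assert len(out) == 1
        assert out[0].dyad_states == tuple("MUHMU")
        assert out[0].control_c_total == 10

    def test_conflicting_site_becomes_ambiguous_on_tie(self):
        recs = [self._rec("MUHMU"), self._rec("UUHMU")]
        (out,) = hf.dedup_umi(recs)
        assert out.dyad_states == (".",) + tuple("UHMU")

    def test_majority_wins_over_minority(self):
        recs = [self._rec("MUHMU"), self._rec("MUHMU"), self._rec("UUHMU")]
        (out,) = hf.dedup_umi(recs)
        assert out.dyad_states == tuple("MUHMU")

    def test_distinct_umis_stay_separate(self):
        recs = [self._rec("MUHMU", umi="AAAAAAAA"), self._rec("MUHMU", umi="TTTTTTTT")]
        assert len(hf.dedup_umi(recs)) == 2

    def test_idempotent_and_order_independent(self):
        recs = [
            self._rec("MUHMU"),
            self._rec("UUHMU"),
            self._rec("MMMMM", umi="TTTTTTTT"),
            self._rec("HHHHH", sample="s2"),
        ]
        once = hf.dedup_umi(recs)
        assert hf.dedup_umi(once) == once
        assert hf.dedup_umi(list(reversed(recs))) == once


class TestTallyCounts:
    def test_uniform_methylated_molecules(self):
        recs = [
            hf.MoleculeRecord("s1", f"U{i}", tuple("MMMMM"), 10, 0) for i in range(10)
        ]
        df, rate = hf.tally_counts(recs)
        row = df.iloc[0]
        assert (row["M"], row["U"], row["H"]) == (50, 0, 0)
        assert row["n_control"] == 100 and rate == 0.0

    def test_ambiguous_states_never_counted(self):
        recs = [hf.MoleculeRecord("s1", "U1", ("M", ".", ".", "U", "H"), 0, 0)]
        df, _ = hf.tally_counts(recs)
        assert df.iloc[0][["M", "U", "H"]].sum() == 3

    def test_control_rate_is_simple_ratio(self):
        recs = [hf.MoleculeRecord("s1", "U1", tuple("MMMMM"), 10_000, 39)]
        _, rate = hf.tally_counts(recs)
        assert rate == pytest.approx(0.0039)

    def test_zero_informative_individual_excluded(self):
        recs = [
            hf.MoleculeRecord("s1", "U1", tuple("MMMMM"), 0, 0),
            hf.MoleculeRecord("s2", "U2", (".", ".", ".", ".", "."), 0, 0),
        ]
        df, _ = hf.tally_counts(recs)
        assert df["sample_id"].tolist() == ["s1"]


class TestRoundTrip:
    def test_zero_error_recovery_is_exact(self, reference, clean_spec):
        reads, truth = _clean_reads(reference, clean_spec)
        records, qc = hf.fold_reads(reads, LINKER, *reference)
        assert qc["ok"] == len(reads)
        assert len(records) == len(truth)
        for rec in records:
            assert rec.dyad_states == truth[(rec.sample_id, rec.umi)]

    def test_slippage_keeps_most_molecules_fully_correct(self, reference):
        """At 5% slippage, >= 95% of molecules retain exact dyad calls."""
        spec = sd.SimSpec(n_individuals_per_group=4, molecules_per_individual=50,
                          fail_rate=0.0, inappropriate_rate=0.0,
                          slippage_rate=0.05, seed=3)
        reads, truth = _clean_reads(reference, spec)
        records, _ = hf.fold_reads(reads, LINKER, *reference)
        correct = sum(
            truth.get((r.sample_id, r.umi)) == r.dyad_states for r in records
        )
        assert correct >= 0.95 * len(truth)
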