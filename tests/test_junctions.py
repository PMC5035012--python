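"""Copy discovery, junction-offset calling and specificity classification."""

import numpy as np
import pytest

from r2scan.io import random_dna, revcomp
from r2scan.junctions import (FlankHit, JunctionCall, call_junctions,
                              classify_family, detect_target_like_utr,
                              find_copies, find_motif)
from r2scan.syngenome import (InsertionSpec, build_target_reference,
                              insert_copies, simulate_element_family)


class TestFindCopies:
    def test_consensus_vs_itself_is_one_full_copy(self, families):
        cons = families["R2A"].consensus
        (c,) = find_copies(cons, cons, family_id="self")
        assert (c.start, c.end) == (0, len(cons))
        assert c.identity_to_consensus == 1.0 and c.strand == "+"

    def test_empty_genome_or_consensus_rejected(self, families):
        with pytest.raises(ValueError):
            find_copies("", families["R2A"].consensus)
        with pytest.raises(ValueError):
            find_copies({"chr": "ACGT" * 100}, "")

    def test_genome_without_insertions_yields_nothing(self, target, families):
        b = insert_copies(target, [], [], n_units=3, spacer_len=300, seed=1)
        assert find_copies(b.genome, families["R2A"].consensus) == []

    def test_full_recall_and_tight_boundaries_at_5pct_divergence(self, demo_bundle):
        """Every truth row recovered with <=5 bp boundary error."""
        for fid, fam in demo_bundle.families.items():
            copies = find_copies(demo_bundle.genome, fam.consensus,
                                 family_id=fid, min_len=500)
            truth = demo_bundle.truth[demo_bundle.truth.family_id == fid]
            assert len(copies) == len(truth)
            for row, copy in zip(truth.itertuples(), copies):
                assert abs(copy.start - row.start) <= 5
                assert abs(copy.end - row.end) <= 5
                assert copy.identity_to_consensus >= 1 - row.divergence - 0.03

    def test_minus_strand_copy_located(self, target, families):
        fam = families["R2C"]
        rng = np.random.default_rng(4)
        genome = random_dna(rng, 500) + revcomp(fam.consensus) + random_dna(rng, 500)
        (c,) = find_copies(genome, fam.consensus, family_id="rc", min_len=500)
        assert c.strand == "-"
        assert (c.start, c.end) == (500, 500 + len(fam.consensus))

    def test_parameter_validation(self, families):
        cons = families["R2A"].consensus
        with pytest.raises(ValueError):
            find_copies(cons, cons, k=4)
        with pytest.raises(ValueError):
            find_copies(cons, cons, min_identity=0.5)


class TestCallJunctions:
    def run_single(self, target, families, spec, seed=5, n_units=1, **kw):
        fam = families[spec.family_id.split("_")[1]]
        b = insert_copies(target, [fam], [spec], n_units=n_units,
                          spacer_len=400, seed=seed)
        (c,) = find_copies(b.genome, fam.consensus,
                           family_id=spec.family_id, min_len=500)
        return call_junctions(c, b.genome, target, **kw)

    def test_canonical_round_trip(self, target, families):
        jc = self.run_single(target, families, InsertionSpec("fam_R2A"))
        assert (jc.offset5, jc.offset3) == (0, 0)
        assert jc.specificity == "canonical"

    @pytest.mark.parametrize("offset5", [15, 110, 130])
    def test_shifted_insertions_recover_configured_offset(self, target, families,
                                                          offset5):
        jc = self.run_single(target, families,
                             InsertionSpec("fam_R2B", offset5=offset5))
        assert jc.offset5 == offset5 and jc.offset3 == 0
        assert jc.specificity == "shifted_5prime"

    def test_spacer_copy_is_non_adjacent(self, target, families):
        """Random spacer flanks stay far below the 0.8 identity threshold."""
        worst = 0.0
        for seed in range(40):
            jc = self.run_single(
                target, families,
                InsertionSpec("fam_R2D", nonspecific=True), seed=seed,
                n_units=2)
            assert jc.specificity == "non_adjacent"
            assert jc.offset5 is None and jc.offset3 is None
            for hit in (jc.flank5_hit, jc.flank3_hit):
                if hit is not None:
                    worst = max(worst, hit.identity)
        assert worst < 0.8

    def test_minus_strand_copy_same_offsets(self, target, families):
        fam = families["R2B"]
        b = insert_copies(target, [fam], [InsertionSpec("fam_R2B", offset5=110)],
                          n_units=1, spacer_len=400, seed=5)
        flipped = {"rdna_array": revcomp(b.genome["rdna_array"])}
        (c,) = find_copies(flipped, fam.consensus, family_id="fam_R2B",
                           min_len=500)
        assert c.strand == "-"
        jc = call_junctions(c, flipped, target)
        assert jc.offset5 == 110 and jc.offset3 == 0
        assert jc.specificity == "shifted_5prime"

    def test_truncated_copy_junctions_unchanged(self, target, families):
        jc = self.run_single(target, families,
                             InsertionSpec("fam_R2A", truncate5=1200))
        assert (jc.offset5, jc.offset3) == (0, 0)
        assert jc.specificity == "canonical"

    def test_offset_recovery_under_divergence(self, target, families):
        """Configured offsets recovered within +-3 bp in >=95% of decayed trials."""
        ok = 0
        trials = 40
        for seed in range(trials):
            jc = self.run_single(
                target, families,
                InsertionSpec("fam_R2C", offset5=110, divergence=0.05),
                seed=seed)
            if jc.offset5 is not None and abs(jc.offset5 - 110) <= 3 \
                    and jc.offset3 == 0:
                ok += 1
        assert ok / trials >= 0.95

    def test_window_validation(self, target, families):
        with pytest.raises(ValueError):
            self.run_single(target, families, InsertionSpec("fam_R2A"), window=10)


class TestClassifyFamily:
    def make_call(self, spec, offset5=0):
        hit = FlankHit(projected=0, identity=0.99, aligned_cols=60, unaligned_gap=0)
        return JunctionCall(copy_id="c", flank5_hit=hit, flank3_hit=hit,
                            offset5=offset5 if spec != "non_adjacent" else None,
                            offset3=0 if spec != "non_adjacent" else None,
                            specificity=spec)

    def test_all_canonical_is_target_specific(self):
        fs = classify_family([self.make_call("canonical")] * 10)
        assert fs.verdict == "target_specific" and fs.modal_offset5 == 0

    def test_one_adjacent_of_two_is_partially_specific(self):
        fs = classify_family([self.make_call("canonical"),
                              self.make_call("non_adjacent")])
        assert fs.verdict == "partially_specific"
        assert (fs.n_adjacent, fs.n_non_adjacent) == (1, 1)

    def test_all_non_adjacent_is_non_specific(self):
        fs = classify_family([self.make_call("non_adjacent")] * 30)
        assert fs.verdict == "non_specific" and fs.n_adjacent == 0
        assert fs.modal_offset5 is None

    def test_modal_offset_ties_take_smallest(self):
        calls = [self.make_call("shifted_5prime", o) for o in (110, 130, 130, 110)]
        assert classify_family(calls).modal_offset5 == 110

    def test_requires_at_least_one_call(self):
        with pytest.raises(ValueError):
            classify_family([])


class TestUtrDetection:
    def test_degraded_segment_flagged_as_utr_internal(self, target, families):
        m = detect_target_like_utr(families["R2B"], target, flank_identity=0.99)
        assert m.is_utr_internal
        assert m.identity < 0.99
        s, e = families["R2B"].utr3_segment
        assert m.utr_interval[0] >= s - 5 and m.utr_interval[1] <= e + 5

    def test_family_without_segment_has_no_hit(self, target, families):
        m = detect_target_like_utr(families["R2A"], target, flank_identity=0.99)
        assert not m.is_utr_internal and m.identity is None

    def test_perfect_copy_indistinguishable_from_flank(self, target, families):
        fam = simulate_element_family("R2B", seed=30, target=target,
                                      utr3_target_segment=(150, 1.0))
        m = detect_target_like_utr(fam, target, flank_identity=1.0)
        assert m.identity == 1.0
        assert not m.is_utr_internal  # strict inequality: cannot be separated

    def test_short_consensus_rejected(self, target):
        with pytest.raises(ValueError):
            detect_target_like_utr("ACGT" * 50, target, flank_identity=1.0)


class TestFindMotif:
    def test_published_avian_geometry(self):
        seq = "A" * 36 + "CCTCCTCGTGG" + "G" * 50
        assert find_motif(seq, "CCTCCTCGTGG") == [(37, 47)]

    def test_rna_and_dna_equivalent(self):
        seq = "AACCUCCUCGUGGAA"
        assert find_motif(seq, "CCTCCTCGTGG") == [(3, 13)]

    def test_absent_motif(self):
        assert find_motif("ACGT" * 30, "CCTCCTCGTGG") == []

    def test_agrees_with_naive_scan_including_overlaps(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
            motif = seq[50:53]
            naive = [(i + 1, i + 3) for i in range(len(seq) - 2)
                     if seq[i:i + 3] == motif]
            assert find_motif(seq, motif) == naive
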