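"""Read filtering, anchored assignment, isoform classification and
profile normalization."""

import numpy as np
import pandas as pd
import pytest

from mirarmkit import isomir, synthetic
from mirarmkit.isomir import (
    IsomirCall,
    MatureReference,
    ReferenceError_,
    assign_reads,
    build_profile,
    classify_isoform,
    compare_profiles,
    dinucleotide_entropy,
    filter_reads,
    normalize_libraries,
)


@pytest.fixture()
def ref():
    # 25-nt flanks around a 22-nt mature
    up = "GGCUAGCUAGCUAGGCCGAUCGAUA"
    mature = "UGAGGUAGUAGGUUGUAUAGUU"
    down = "GCCAGCUAACUAUACAAUCUACUGU"
    return MatureReference("let-7", mature, up + mature + down, 25)


class TestFilterReads:
    def test_minimum_length_boundary(self):
        reads = [("short", "ACGUACGUACGUA"), ("ok", "ACGUACGUACGUAC")]
        kept, stats = filter_reads(reads, min_len=14, entropy_cutoff=0.0)
        assert [r[0] for r in kept] == ["ok"]
        assert stats["fraction_removed"] == pytest.approx(0.5)

    def test_homopolymer_removed_at_any_positive_cutoff(self):
        assert dinucleotide_entropy("A" * 16) == 0.0
        kept, _ = filter_reads([("homo", "A" * 16)], entropy_cutoff=1e-6)
        assert kept == []

    def test_synthetic_library_loses_under_one_percent(self, small_config, references):
        mats, precs, _, _ = references
        reads, _ = synthetic.gen_small_rna_reads(small_config, precs, mats)
        _, stats = filter_reads(reads)
        assert stats["fraction_removed"] < 0.01


class TestAssignReads:
    def test_exact_mature_read(self, ref):
        calls = assign_reads([("r1", ref.mature)], [ref])
        assert len(calls) == 1
        c = calls[0]
        assert (c.mirna_id, c.mismatches, c.weight, c.isoform_class) == ("let-7", 0, 1.0, "canonical")

    def test_three_substitutions_unassigned(self, ref):
        read = "CAU" + ref.mature[3:]  # 3 mismatches at the 5' end
        assert assign_reads([("r1", read)], [ref], genome_filter=False) == []

    def test_identical_references_split_weight(self, ref):
        twin = MatureReference("let-7-twin", ref.mature, ref.precursor, ref.mature_start)
        calls = assign_reads([("r1", ref.mature)], [ref, twin])
        assert len(calls) == 2
        assert all(c.weight == pytest.approx(0.5) for c in calls)
        assert sum(c.weight for c in calls) == pytest.approx(1.0)

    def test_max_hits_discards_promiscuous_reads(self, ref):
        clones = [
            MatureReference(f"m{i}", ref.mature, ref.precursor, ref.mature_start)
            for i in range(5)
        ]
        assert assign_reads([("r1", ref.mature)], clones, max_hits=4) == []

    def test_empty_reference_set_rejected(self, ref):
        with pytest.raises(ReferenceError_):
            assign_reads([("r1", ref.mature)], [])

    def test_matches_brute_force_all_windows_scan(self, references):
        """The anchored matcher equals an independent exhaustive scan over
        every (reference, 5' offset) placement."""
        mats, precs, _, _ = references
        refs = isomir.references_from_tables(mats, precs)
        cfg = synthetic.SimConfig(seed=17, n_reads=300, read_error_rate=0.005)
        reads, _ = synthetic.gen_small_rna_reads(cfg, precs, mats)

        def norm(s):
            return s.upper().replace("U", "T")

        def brute(read):
            read = norm(read)
            hits = []
            for r in refs:
                prec = norm(r.precursor)
                best = None
                for off in range(-3, 4):
                    g = r.mature_start + off
                    if g < 0:
                        continue
                    core = r.mature_start + len(r.mature) - g
                    if core <= 0:
                        continue
                    ov = min(len(read), core)
                    mm = sum(a != b for a, b in zip(read[:ov], prec[g : g + ov]))
                    if mm > 2:
                        continue
                    trim = core - len(read) if len(read) < core else 0
                    tail = len(read) - core if len(read) > core else 0
                    key = (mm, abs(off), trim + tail)
                    if best is None or key < best[0]:
                        best = (key, r.mirna_id, off)
                if best:
                    hits.append((best[0][0], best[1], best[2]))
            if not hits:
                return []
            mmin = min(h[0] for h in hits)
            return sorted((h[1], h[2]) for h in hits if h[0] == mmin)

        calls = assign_reads(reads, refs, genome_filter=False)
        by_read = {}
        for c in calls:
            by_read.setdefault(c.read_id, []).append((c.mirna_id, c.offset_5p))
        for rid, seq in reads:
            assert sorted(by_read.get(rid, [])) == brute(seq), (rid, seq)


class TestClassifyIsoform:
    def mk(self, trim=0, tail="", off=0):
        return IsomirCall("r", "let-7", 0, off, trim, tail, "none", "canonical")

    def test_canonical(self, ref):
        assert classify_isoform(self.mk(), ref).isoform_class == "canonical"

    def test_trimmed_two(self, ref):
        c = classify_isoform(self.mk(trim=2), ref)
        assert (c.isoform_class, c.tail_type) == ("trimmed", "none")

    def test_non_templated_tail(self, ref):
        # downstream context starts with "GC": an "AA" tail matches nowhere
        c = classify_isoform(self.mk(tail="AA"), ref)
        assert (c.isoform_class, c.tail_type) == ("tailed", "non_templated")

    def test_templated_tail(self, ref):
        c = classify_isoform(self.mk(tail="GC"), ref)
        assert c.tail_type == "templated"

    def test_mixed_tail(self, ref):
        c = classify_isoform(self.mk(tail="GA"), ref)
        assert c.tail_type == "mixed"

    def test_five_prime_variant_overrides(self, ref):
        c = classify_isoform(self.mk(trim=1, off=1), ref)
        assert c.isoform_class == "five_prime_variant"

    def test_trimmed_and_tailed(self, ref):
        c = classify_isoform(self.mk(trim=1, tail="AA"), ref)
        assert c.isoform_class == "trimmed_tailed"

    def test_missing_context_rejected(self):
        bare = MatureReference("m", "ACGUACGUACGUACGUACGU", "ACGUACGUACGUACGUACGU", 0)
        with pytest.raises(ReferenceError_):
            classify_isoform(self.mk(tail="AAA"), bare)

    def test_round_trip_against_generator_labels(self, small_config, references):
        mats, precs, _, _ = references
        reads, truth = synthetic.gen_small_rna_reads(small_config, precs, mats)
        refs = isomir.references_from_tables(mats, precs)
        calls = assign_reads(reads, refs)
        want = {
            "canonical": ("canonical", "none"),
            "trimmed": ("trimmed", "none"),
            "tailed_nt": ("tailed", "non_templated"),
            "tailed_t": ("tailed", "templated"),
        }
        assert len(calls) == len(reads)
        for c in calls:
            mid, cls = truth.isoform_labels[c.read_id]
            assert c.mirna_id == mid
            assert (c.isoform_class, c.tail_type) == want[cls]


class TestProfiles:
    def test_proportions_sum_to_one_and_weights_conserved(self, small_config, references):
        mats, precs, _, _ = references
        reads, _ = synthetic.gen_small_rna_reads(small_config, precs, mats)
        refs = isomir.references_from_tables(mats, precs)
        calls = assign_reads(reads, refs)
        profile = build_profile(calls)
        assert np.allclose(profile.proportions.sum(axis=1), 1.0)
        n_assigned = len({c.read_id for c in calls})
        assert profile.counts.to_numpy().sum() + profile.five_prime_counts.sum() == pytest.approx(
            n_assigned, abs=1e-9
        )

    def test_normalization_hand_example(self):
        counts = pd.DataFrame({"lib1": [10.0], "lib2": [10.0]}, index=["m"])
        norm = normalize_libraries(counts, {"lib1": 100.0, "lib2": 200.0})
        # 10/100 * 150 = 15 -> log2(16) = 4
        assert norm.loc["m", "lib1"] == pytest.approx(4.0)

    def test_single_library_normalization_is_identity_scale(self):
        counts = pd.DataFrame({"lib": [7.0, 0.0]}, index=["a", "b"])
        norm = normalize_libraries(counts, {"lib": 50.0})
        assert norm.loc["a", "lib"] == pytest.approx(np.log2(8.0))
        assert norm.loc["b", "lib"] == 0.0

    def test_proportions_invariant_to_library_scaling(self, small_config, references):
        mats, precs, _, _ = references
        reads, _ = synthetic.gen_small_rna_reads(small_config, precs, mats)
        refs = isomir.references_from_tables(mats, precs)
        calls = assign_reads(reads, refs)
        p1 = build_profile(calls).proportions
        doubled = [
            IsomirCall(c.read_id, c.mirna_id, c.mismatches, c.offset_5p, c.trim_3p,
                       c.tail, c.tail_type, c.isoform_class, c.weight * 2)
            for c in calls
        ]
        p2 = build_profile(doubled).proportions
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_library_total_rejected(self):
        with pytest.raises(ReferenceError_):
            normalize_libraries(pd.DataFrame({"lib": [1.0]}), {"lib": 0.0})


class TestCompareProfiles:
    def make_profile(self, trim_prop, n=10000):
        counts = pd.DataFrame(
            {
                "canonical": [n * (1 - trim_prop)],
                "trimmed": [n * trim_prop],
                "tailed": [0.0],
                "trimmed_tailed": [0.0],
            },
            index=pd.Index(["m"], name="mirna_id"),
        )
        props = counts.div(counts.sum(axis=1), axis=0)
        return isomir.IsomirProfile(counts, props, pd.Series(0.0, index=counts.index))

    def test_identical_profiles_have_zero_deltas(self):
        p = self.make_profile(0.2)
        res = compare_profiles(p, p)
        assert np.allclose(res["delta"], 0.0)

    def test_planted_trimming_shift_detected(self):
        res = compare_profiles(self.make_profile(0.2), self.make_profile(0.4))
        row = res[res["isoform_class"] == "trimmed"].iloc[0]
        assert row["delta"] == pytest.approx(0.2)
        assert row["p_value"] < 1e-6
        assert bool(row["increased"]) is True

    def test_swapped_arguments_negate_deltas(self):
        a, b = self.make_profile(0.2), self.make_profile(0.35)
        d1 = compare_profiles(a, b)["delta"].to_numpy()
        d2 = compare_profiles(b, a)["delta"].to_numpy()
        assert np.allclose(d1, -d2)

    def test_mismatched_class_sets_rejected(self):
        a = self.make_profile(0.2)
        b = self.make_profile(0.2)
        b.counts.columns = ["c1", "c2", "c3", "c4"]
        with pytest.raises(ReferenceError_):
            compare_profiles(a, b)
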