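"""Read-pair merging, window extraction, and variant classification."""

import numpy as np
import pytest
from scipy import stats as sps

from phagescape.amplicon import (
    ACCEPTED,
    COMPLEX,
    MULTIPLE_SUBSTITUTION,
    REJECTED_DISCORDANT,
    REJECTED_UNALIGNABLE,
    SINGLE_DELETION,
    SINGLE_SUBSTITUTION,
    WILDTYPE,
    EmptySampleError,
    classify_pairs,
    classify_window,
    extract_window,
    fraction_mutated,
    merge_pair,
    reverse_complement,
    status_counts,
    tabulate,
)
from phagescape.synthetic import emit_amplicon_reads, sample_population


def mutate(seq: str, off: int, base: str = None) -> str:
    alt = base or {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[off]]
    return seq[:off] + alt + seq[off + 1 :]


class TestExtractWindow:
    def test_reference_amplicon_yields_reference_window(self, spec):
        assert extract_window(spec.amplicon_reference, spec) == spec.reference_window
        assert len(spec.reference_window) == 24

    def test_deletion_shortens_returned_window(self, spec):
        win = spec.reference_window
        read = (
            spec.amplicon_reference[: spec.window_start]
            + win[:10] + win[11:]
            + spec.amplicon_reference[spec.window_end :]
        )
        assert len(extract_window(read, spec)) == 23

    def test_single_anchor_mismatch_tolerated(self, spec):
        read = mutate(spec.amplicon_reference, spec.window_start - 3)
        assert extract_window(read, spec) == spec.reference_window

    @pytest.mark.parametrize("positions", [(0, 1), (2, 5), (1, 7)])
    def test_two_anchor_mismatches_unalignable(self, spec, positions):
        read = spec.amplicon_reference
        base = spec.window_start - len(spec.flank_anchor_left)
        for p in positions:
            read = mutate(read, base + p)
        assert extract_window(read, spec) is None

    def test_duplicated_anchor_is_ambiguous(self, spec):
        read = spec.amplicon_reference + spec.flank_anchor_left
        assert extract_window(read, spec) is None

    def test_out_of_order_anchors_fail(self, spec):
        read = spec.flank_anchor_right + spec.flank_anchor_left
        assert extract_window(read, spec) is None


class TestMergePair:
    def test_concordant_pair_accepted(self, spec, make_pair):
        r1, r2 = make_pair(spec, spec.reference_window)
        call = merge_pair(r1, r2, spec)
        assert call.status == ACCEPTED
        assert call.window_sequence == spec.reference_window

    def test_single_base_disagreement_rejected(self, spec, make_pair):
        r1, r2 = make_pair(spec, spec.reference_window)
        r1 = mutate(r1, spec.window_start + 5)
        assert merge_pair(r1, r2, spec).status == REJECTED_DISCORDANT

    def test_r1_fallback_when_r2_misses_window(self, spec, make_pair):
        r1, r2 = make_pair(spec, spec.reference_window)
        call = merge_pair(r1, r2[:20], spec)  # truncated R2 never reaches the window
        assert call.status == ACCEPTED
        assert call.window_sequence == spec.reference_window

    def test_neither_read_covering_window_unalignable(self, spec):
        assert merge_pair("ACGTACGT", "ACGTACGT", spec).status == REJECTED_UNALIGNABLE

    def test_concordance_filter_can_be_disabled(self, spec, make_pair):
        r1, r2 = make_pair(spec, spec.reference_window)
        r1 = mutate(r1, spec.window_start + 5)
        call = merge_pair(r1, r2, spec, require_concordance=False)
        assert call.status == ACCEPTED
        assert call.window_sequence == extract_window(r1, spec)


class TestClassifyWindow:
    def test_reference_window_is_wildtype(self, spec):
        call = classify_window(spec.reference_window, spec)
        assert call.variant_class == WILDTYPE
        assert call.variants == []

    def test_single_substitution_gets_pam_relative_label(self, spec):
        win = mutate(spec.reference_window, spec.offset_of(2), "T")
        call = classify_window(win, spec)
        assert call.variant_class == SINGLE_SUBSTITUTION
        (v,) = call.variants
        assert v.position.index == 2
        assert v.alt_base == "T"
        assert v.label == f"{spec.reference_window[spec.offset_of(2)]}2T"

    def test_pam_substitution_labelled_negative(self, spec):
        win = mutate(spec.reference_window, spec.offset_of(-2), "C")
        (v,) = classify_window(win, spec).variants
        assert v.position.index == -2
        assert v.label == "T-2C"  # PAM is TTTA, position -2 is the third T

    def test_two_substitutions_are_multiple(self, spec):
        win = mutate(mutate(spec.reference_window, 6), 15)
        call = classify_window(win, spec)
        assert call.variant_class == MULTIPLE_SUBSTITUTION
        assert len(call.variants) == 2

    def test_every_single_deletion_is_called_with_unique_canonical_label(self, spec):
        # enumerate all 24 single-base deletions; deletions of different
        # bases within one homopolymer run must collapse to one label, and
        # the canonical label must sit 3' of the run (clamped at the edge)
        ref = spec.reference_window
        L = len(ref)
        for i in range(L):
            window = ref[:i] + ref[i + 1 :]
            # independent oracle: all placements producing this window
            placements = [j for j in range(L) if ref[:j] + ref[j + 1 :] == window]
            call = classify_window(window, spec)
            assert call.variant_class == SINGLE_DELETION
            expected_offset = min(max(placements) + 1, L - 1)
            assert spec.offset_of(call.variants[0].position.index) == expected_offset
            alt_offset = min(max(placements), L - 1)
            assert spec.offset_of(call.alt_deletion_variant.position.index) == alt_offset

    def test_homopolymer_deletion_label_independent_of_excised_base(self, spec):
        # synthetic window with an internal CC run on the demo protospacer
        ref = spec.reference_window
        run_start = None
        for i in range(len(ref) - 1):
            if ref[i] == ref[i + 1]:
                run_start = i
                break
        if run_start is None:
            pytest.skip("demo window has no homopolymer run")
        del_a = ref[:run_start] + ref[run_start + 1 :]
        del_b = ref[: run_start + 1] + ref[run_start + 2 :]
        assert del_a == del_b
        call = classify_window(del_a, spec)
        assert call.variant_class == SINGLE_DELETION

    def test_multi_nucleotide_deletion_is_complex(self, spec):
        win = spec.reference_window[:5] + spec.reference_window[8:]
        assert classify_window(win, spec).variant_class == COMPLEX

    def test_non_acgt_rejected(self, spec):
        win = "N" + spec.reference_window[1:]
        assert classify_window(win, spec).status == REJECTED_UNALIGNABLE


class TestTabulate:
    def test_single_variant_proportion(self, spec):
        calls = [classify_window(spec.reference_window, spec) for _ in range(9)]
        calls.append(classify_window(mutate(spec.reference_window, spec.offset_of(2), "T"), spec))
        m = tabulate(calls, spec)
        assert m.n_accepted == 10
        assert m.proportions.loc[2] == pytest.approx(0.1)
        assert m.proportions.drop(2).eq(0).all()

    def test_multiple_substitution_increments_every_position(self, spec):
        calls = [classify_window(spec.reference_window, spec) for _ in range(9)]
        win = mutate(mutate(spec.reference_window, spec.offset_of(14)), spec.offset_of(18))
        calls.append(classify_window(win, spec))
        m = tabulate(calls, spec)
        assert m.proportions.loc[14] == pytest.approx(0.1)
        assert m.proportions.loc[18] == pytest.approx(0.1)

    def test_matches_brute_force_recount(self, spec):
        # random windows with random substitutions, recounted independently
        rng = np.random.default_rng(17)
        ref = spec.reference_window
        calls = []
        expected = {p: 0 for p in spec.positions_by_index()}
        for _ in range(300):
            win = ref
            k = rng.integers(0, 4)
            offsets = rng.choice(len(ref), size=k, replace=False)
            for off in offsets:
                win = mutate(win, int(off))
            calls.append(classify_window(win, spec))
            for off in offsets:
                expected[spec.label_at(int(off)).index] += 1
        m = tabulate(calls, spec)
        for p, count in expected.items():
            assert m.proportions.loc[p] == pytest.approx(count / 300)

    def test_by_type_sums_to_position_total(self, spec):
        rng = np.random.default_rng(23)
        calls = []
        for _ in range(100):
            win = spec.reference_window
            if rng.random() < 0.5:
                win = mutate(win, int(rng.integers(24)))
            calls.append(classify_window(win, spec))
        m = tabulate(calls, spec)
        assert np.allclose(m.by_type.sum(axis=1).to_numpy(), m.proportions.to_numpy())

    def test_empty_sample_signalled(self, spec):
        with pytest.raises(EmptySampleError):
            tabulate([], spec)


class TestFractionMutated:
    def test_mixture_fraction(self, spec):
        calls = [classify_window(spec.reference_window, spec) for _ in range(80)]
        calls += [classify_window(mutate(spec.reference_window, 6), spec) for _ in range(20)]
        assert fraction_mutated(calls) == pytest.approx(0.20)

    def test_all_wildtype_is_zero(self, spec):
        calls = [classify_window(spec.reference_window, spec) for _ in range(5)]
        assert fraction_mutated(calls) == 0.0

    def test_simulated_mixture_within_binomial_interval(self, spec):
        mut = mutate(spec.reference_window, spec.offset_of(2), "T")
        counts = sample_population({spec.reference_window: 0.65, mut: 0.35}, 5000, seed=3)
        r1, r2, _ = emit_amplicon_reads(counts, spec, read_length=75, seed=3)
        calls = classify_pairs(
            [(a.read_id, a.sequence, b.sequence) for a, b in zip(r1, r2)], spec
        )
        lo, hi = sps.binom.ppf([0.005, 0.995], 5000, 0.35) / 5000
        assert lo <= fraction_mutated(calls) <= hi


class TestPipelineInvariants:
    def test_statuses_partition_all_pairs(self, spec):
        r1, r2, _ = emit_amplicon_reads(
            {spec.reference_window: 500}, spec, read_length=75,
            seq_error_rate=0.01, discordance_rate=0.1, seed=7,
        )
        calls = classify_pairs(
            [(a.read_id, a.sequence, b.sequence) for a, b in zip(r1, r2)], spec
        )
        counts = status_counts(calls)
        assert sum(counts.values()) == 500
        assert all(c.status in counts for c in calls)

    def test_error_free_reads_round_trip_to_planted_spectrum(self, spec):
        mut = mutate(spec.reference_window, spec.offset_of(5))
        deletion = spec.reference_window[:8] + spec.reference_window[9:]
        counts = {spec.reference_window: 120, mut: 60, deletion: 20}
        r1, r2, _ = emit_amplicon_reads(counts, spec, read_length=75, seed=0)
        calls = classify_pairs(
            [(a.read_id, a.sequence, b.sequence) for a, b in zip(r1, r2)], spec
        )
        observed = {}
        for c in calls:
            assert c.status == ACCEPTED
            observed[c.window_sequence] = observed.get(c.window_sequence, 0) + 1
        assert observed == counts

    def test_all_planted_discordant_pairs_rejected(self, spec):
        r1, r2, truth = emit_amplicon_reads(
            {spec.reference_window: 1000}, spec, read_length=75,
            discordance_rate=0.1, seed=13,
        )
        calls = classify_pairs(
            [(a.read_id, a.sequence, b.sequence) for a, b in zip(r1, r2)], spec
        )
        flagged = set(truth.loc[truth["discordant"] == 1, "read_id"])
        rejected = {c.read_id for c in calls if c.status == REJECTED_DISCORDANT}
        assert flagged <= rejected
        assert rejected == flagged  # error-free run: only planted pairs rejected
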