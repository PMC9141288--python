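"""Per-locus state calling, TSD detection, criteria, and annotation readers."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import retrophylo as rp
from retrophylo.locus_diagnostics import call_states, detect_tsd, validate_marker
from retrophylo.msc_simulator import LocusSimConfig, simulate_locus

TAXA = ["Primates", "Dermoptera", "Scandentia", "Glires", "Bos_taurus"]
OUT = ["Bos_taurus"]


def planted(seed=0, present=("Primates", "Dermoptera"), shifted=None, **kw):
    plan = {t: t in present for t in TAXA}
    return simulate_locus(
        LocusSimConfig(seed=seed, **kw), plan, shifted_taxa=shifted,
        outgroup_taxa=OUT,
    )


class TestCallStates:
    def test_clean_locus_matches_planted_truth(self):
        locus, truth = planted(seed=1)
        call = call_states(locus)
        for taxon, t in truth.items():
            assert call.states[taxon].name.lower() == t["state"]

    @pytest.mark.parametrize("shift", [1, 2, 3])
    def test_small_shift_still_absent(self, shift):
        locus, _ = planted(seed=2 + shift, shifted={"Scandentia": shift})
        call = call_states(locus)
        assert call.states["Scandentia"] is rp.MarkerState.ABSENT
        assert call.shift_nt["Scandentia"] == shift

    @pytest.mark.parametrize("shift", [4, 5, 8])
    def test_large_shift_is_unknown_never_absent(self, shift):
        locus, _ = planted(seed=10 + shift, shifted={"Scandentia": shift})
        call = call_states(locus)
        assert call.states["Scandentia"] is rp.MarkerState.UNKNOWN

    def test_n_run_is_not_presence(self):
        locus, _ = planted(seed=3)
        te = locus.te
        row = locus.sequences["Primates"]
        locus.sequences["Primates"] = (
            row[: te.start] + "N" * (te.end - te.start) + row[te.end :]
        )
        call = call_states(locus)
        assert call.states["Primates"] is rp.MarkerState.UNKNOWN

    def test_deleted_flank_is_unknown(self):
        locus, _ = planted(seed=4)
        te = locus.te
        row = locus.sequences["Scandentia"]
        # absence gap chewing far into the left flank
        locus.sequences["Scandentia"] = (
            "-" * te.start + row[te.start:]
        )
        call = call_states(locus)
        assert call.states["Scandentia"] is rp.MarkerState.UNKNOWN

    def test_short_row_raises(self):
        locus, _ = planted(seed=5)
        locus.sequences["Primates"] = locus.sequences["Primates"][:-1]
        with pytest.raises(ValueError):
            call_states(locus)


class TestDetectTsd:
    @given(length=st.integers(4, 25))
    def test_recovers_planted_length_exhaustively(self, length):
        locus, _ = planted(
            seed=100 + length, tsd_length=length, substitution_rate=0.0
        )
        tsd = detect_tsd(locus, "Primates", max_mismatch=0)
        assert tsd is not None and tsd.length == length

    def test_exhaustive_window_oracle(self):
        """Longest flanking direct repeat agrees with a brute-force scan."""
        locus, _ = planted(seed=6, substitution_rate=0.0)
        te = locus.te
        row = locus.sequences["Primates"]
        left = row[: te.start].replace("-", "")
        right = row[te.end :].replace("-", "")
        best = 0
        for L in range(4, 26):
            if left[-L:] == right[:L]:
                best = max(best, L)
        tsd = detect_tsd(locus, "Primates", max_mismatch=0)
        assert tsd.length == best

    def test_absent_in_random_flanks(self):
        locus, _ = planted(seed=7)
        te = locus.te
        # scramble the right flank so no repeat of the left remains
        row = locus.sequences["Primates"]
        locus.sequences["Primates"] = row[: te.end] + "A" * (len(row) - te.end)
        locus.sequences["Dermoptera"] = (
            locus.sequences["Dermoptera"][: te.end] + "C" * (len(row) - te.end)
        )
        assert detect_tsd(locus, "Primates", max_mismatch=0) is None

    def test_one_mismatch_tolerated(self):
        locus, _ = planted(seed=8, substitution_rate=0.0)
        te = locus.te
        row = locus.sequences["Primates"]
        i = te.start - 3
        base = "A" if row[i] != "A" else "C"
        locus.sequences["Primates"] = row[:i] + base + row[i + 1 :]
        assert detect_tsd(locus, "Primates", max_mismatch=0) is None or \
            detect_tsd(locus, "Primates", max_mismatch=0).length < 12
        tsd = detect_tsd(locus, "Primates", max_mismatch=1)
        assert tsd is not None and tsd.length == 12


class TestValidateMarker:
    def test_clean_locus_accepted(self):
        locus, _ = planted(seed=9)
        call = validate_marker(call_states(locus), locus)
        assert call.accepted
        assert all(call.criteria_flags[i] for i in (1, 2, 3, 4))
        assert call.tsd is not None

    def test_outgroup_presence_rejected(self):
        locus, _ = planted(seed=10, present=("Primates", "Dermoptera", "Bos_taurus"))
        call = validate_marker(call_states(locus), locus)
        assert not call.accepted
        assert call.criteria_flags[4] is False

    def test_conflicting_orientation_rejected(self):
        locus, _ = planted(seed=11)
        locus.te_strands["Dermoptera"] = "-"
        call = validate_marker(call_states(locus), locus)
        assert not call.accepted
        assert call.criteria_flags[3] is False

    def test_conflicting_family_rejected(self):
        locus, _ = planted(seed=12)
        locus.te_families["Dermoptera"] = "L1MB5#LINE/L1"
        call = validate_marker(call_states(locus), locus)
        assert not call.accepted
        assert call.criteria_flags[2] is False

    def test_missing_outgroup_not_accepted(self):
        locus, _ = planted(seed=13)
        del locus.sequences["Bos_taurus"]
        call = validate_marker(call_states(locus), locus)
        assert not call.accepted
        assert call.criteria_flags[4] is None
        assert call.reasons

    def test_accepted_implies_prefilter(self):
        """Accepted markers always satisfy >=2 present and >=1 absent."""
        for seed in range(20):
            locus, _ = planted(seed=seed)
            call = validate_marker(call_states(locus), locus)
            if call.accepted:
                present = sum(
                    s is rp.MarkerState.PRESENT for s in call.states.values()
                )
                absent = sum(
                    s is rp.MarkerState.ABSENT for s in call.states.values()
                )
                assert present >= 2 and absent >= 1


class TestLine1Filter:
    @pytest.mark.parametrize("trunc,passes", [(0, True), (25, True), (26, False)])
    def test_boundary_inclusive(self, trunc, passes):
        te = rp.TEAnnotation(
            family="L1MB5#LINE/L1", strand="+", start=0, end=100,
            truncation_3prime=trunc,
        )
        assert rp.line1_filter(te) is passes

    def test_non_line1_rejected(self):
        te = rp.TEAnnotation(family="MER57F#LTR/ERV1", strand="+", start=0, end=10)
        with pytest.raises(ValueError):
            rp.line1_filter(te)


class TestAnnotationReaders:
    def test_bed6_row(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t400\tL1MB5\t0\t+\n")
        (te,) = rp.read_te_annotations(path, "bed")
        assert (te.start, te.end, te.strand, te.family) == (100, 400, "+", "L1MB5")

    def test_repeatmasker_plus_strand_coordinates(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            "   SW  perc perc perc  query     begin end (left) strand repeat "
            "class/family begin end (left) ID\n\n"
            "  239  29.4  1.9  1.0  chr1      101   400 (1000) + "
            "L1MB5 LINE/L1 1 300 (12) 1\n"
        )
        (te,) = rp.read_te_annotations(path, "repeatmasker_out")
        assert (te.start, te.end) == (100, 400)
        assert te.strand == "+"
        assert te.truncation_3prime == 12

    def test_repeatmasker_c_maps_to_minus(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            "  239  29.4  1.9  1.0  chr1      101   400 (1000) C "
            "L1MB5 LINE/L1 (7) 300 1 1\n"
        )
        (te,) = rp.read_te_annotations(path, "repeatmasker_out")
        assert te.strand == "-"
        assert te.truncation_3prime == 7

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t400\tL1MB5\t0\t+\nchr1\tx\t500\tL1\t0\t-\n")
        with pytest.raises(ValueError, match="line 2"):
            rp.read_te_annotations(path, "bed")


class TestSimulatedLocusAccuracy:
    def test_noise_free_calls_are_perfect(self):
        """State calls on 50 clean planted loci match truth exactly."""
        plans = [
            ("Primates", "Dermoptera"),
            ("Primates", "Dermoptera", "Scandentia"),
            ("Dermoptera", "Scandentia"),
        ]
        for seed in range(50):
            locus, truth = planted(
                seed=seed, present=plans[seed % 3], substitution_rate=0.0
            )
            call = call_states(locus)
            for taxon, t in truth.items():
                assert call.states[taxon].name.lower() == t["state"], (
                    seed, taxon,
                )
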