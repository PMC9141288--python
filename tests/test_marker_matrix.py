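"""Marker data model, classification, tabulation, and matrix I/O."""

from itertools import product

import pytest
from hypothesis import given
from hypothesis import strategies as st

import retrophylo as rp
from retrophylo.marker_matrix import (
    Classification,
    MatrixFormatError,
    _state_rows,
    matrix_from_counts,
    y_pattern_order,
)

P, D, S, G = "Primates", "Dermoptera", "Scandentia", "Glires"
STATES = [rp.MarkerState.PRESENT, rp.MarkerState.ABSENT, rp.MarkerState.UNKNOWN]


def make_marker(states, panel, outgroup_absent=True):
    full = dict(zip(panel.ingroup, states))
    if outgroup_absent:
        for o in panel.outgroup:
            full[o] = rp.MarkerState.ABSENT
    return rp.Marker(id="m1", states=full)


def oracle_classify(states):
    """Brute-force restatement of the diagnostic rule."""
    present = {l for l, s in states.items() if s is rp.MarkerState.PRESENT}
    absent = {l for l, s in states.items() if s is rp.MarkerState.ABSENT}
    unknown = {l for l, s in states.items() if s is rp.MarkerState.UNKNOWN}
    if len(present) < 2 or not absent:
        return Classification.UNINFORMATIVE
    if unknown:
        return Classification.PARTIALLY_INFORMATIVE
    return frozenset(present)


class TestClassification:
    def test_matches_bruteforce_oracle_on_all_state_vectors(self, panel):
        """Exhaustive equivalence over all 3^4 ingroup state vectors."""
        for combo in product(STATES, repeat=4):
            marker = make_marker(combo, panel)
            expected = oracle_classify(dict(zip(panel.ingroup, combo)))
            assert rp.classify_marker(marker, panel) == expected

    def test_pair_pattern(self, panel):
        marker = make_marker(
            [rp.MarkerState.ABSENT, rp.MarkerState.PRESENT,
             rp.MarkerState.PRESENT, rp.MarkerState.ABSENT], panel,
        )
        assert rp.classify_marker(marker, panel) == frozenset({D, S})

    def test_all_present_is_uninformative(self, panel):
        marker = make_marker([rp.MarkerState.PRESENT] * 4, panel)
        assert rp.classify_marker(marker, panel) is Classification.UNINFORMATIVE

    def test_single_presence_is_uninformative(self, panel):
        marker = make_marker(
            [rp.MarkerState.PRESENT] + [rp.MarkerState.ABSENT] * 3, panel
        )
        assert rp.classify_marker(marker, panel) is Classification.UNINFORMATIVE

    def test_missing_lineage_raises(self, panel):
        marker = rp.Marker(id="m", states={P: rp.MarkerState.PRESENT})
        with pytest.raises(KeyError):
            rp.classify_marker(marker, panel)


class TestTabulate:
    def test_empty_matrix_is_all_zero(self, panel):
        counts = rp.tabulate(rp.MarkerMatrix([], panel))
        assert counts.total == 0
        assert all(v == 0 for v in counts.counts.values())

    def test_three_identical_markers(self, panel):
        marker_states = [
            rp.MarkerState.ABSENT, rp.MarkerState.PRESENT,
            rp.MarkerState.PRESENT, rp.MarkerState.ABSENT,
        ]
        markers = [
            rp.Marker(id=f"m{i}", states=dict(zip(panel.ingroup, marker_states)))
            for i in range(3)
        ]
        counts = rp.tabulate(rp.MarkerMatrix(markers, panel))
        assert counts[{D, S}] == 3
        assert counts.total == 3

    def test_partition_conservation(self, panel):
        """pattern total + partial + uninformative = matrix size."""
        matrix = rp.simulate_markers(
            rp.SimulationConfig(tau1=0.3, tau2=0.5, n_markers=500,
                                missing_rate=0.2, seed=9)
        )
        counts = rp.tabulate(matrix)
        assert counts.total + counts.n_partial + counts.n_uninformative == 500


class TestCountsSummaries:
    def test_conflicting_total_identity(self, example_counts):
        supported = [{P, D}, {P, D, S}]
        assert rp.conflicting_total(example_counts, supported) == (
            example_counts.total
            - example_counts[{P, D}]
            - example_counts[{P, D, S}]
        )

    def test_conflicting_total_direct_sum(self, panel):
        counts = rp.PatternCounts(
            {frozenset({P, D}): 2, frozenset({P, S}): 1}, panel
        )
        assert rp.conflicting_total(counts, [{P, D}]) == 1
        empty = rp.PatternCounts({}, panel)
        assert rp.conflicting_total(empty, [{P, D}]) == 0

    def test_y_vector_round_trip(self, panel):
        values = tuple(range(1, 11))
        counts = rp.PatternCounts.from_y_vector(values, panel)
        assert counts.y_vector() == values

    def test_y_order_anchors(self, panel):
        """The documented mapping pins the three textual anchors."""
        order = y_pattern_order(panel.ingroup)
        counts = rp.example_counts()
        assert counts[{P, D}] == 132
        assert counts[{P, D, S}] == 94
        assert order.index(frozenset({D, S})) == 3  # y14
        assert counts[{D, S}] == 9


class TestAnnotationConcordance:
    def test_hand_counted(self):
        panel = rp.LineagePanel()
        lag = panel.annotation_lineage
        rows = [
            ("1", "1"), ("0", "0"),            # concordant
            ("1", "0"),                          # conflicting
            ("1", "?"), ("0", "?"),            # unknown
        ]
        markers = []
        for i, (g, l) in enumerate(rows):
            states = {
                P: rp.MarkerState.PRESENT, D: rp.MarkerState.PRESENT,
                S: rp.MarkerState.ABSENT,
                G: rp.MarkerState.from_symbol(g),
                lag: rp.MarkerState.from_symbol(l),
                "Bos_taurus": rp.MarkerState.ABSENT,
            }
            markers.append(rp.Marker(id=f"m{i}", states=states))
        assert rp.annotation_concordance(rp.MarkerMatrix(markers, panel)) == (3, 2)

    def test_all_unknown(self, panel):
        marker = rp.Marker(
            id="m",
            states={
                **{l: rp.MarkerState.PRESENT for l in panel.ingroup},
                panel.annotation_lineage: rp.MarkerState.UNKNOWN,
            },
        )
        assert rp.annotation_concordance(rp.MarkerMatrix([marker], panel)) == (0, 0)


@st.composite
def random_matrix(draw):
    n_taxa = draw(st.integers(2, 7))
    n_markers = draw(st.integers(1, 30))
    taxa = [f"T{i}" for i in range(n_taxa)]
    rows = {
        t: "".join(draw(st.sampled_from("01?")) for _ in range(n_markers))
        for t in taxa
    }
    panel = rp.LineagePanel(
        ingroup=tuple(taxa[: min(4, n_taxa)]),
        annotation_lineage=None,
        outgroup=tuple(taxa[min(4, n_taxa):]),
    )
    markers = [
        rp.Marker(
            id=f"mk{i}",
            states={t: rp.MarkerState.from_symbol(rows[t][i]) for t in taxa},
        )
        for i in range(n_markers)
    ]
    return rp.MarkerMatrix(markers, panel)


class TestMatrixIO:
    @given(matrix=random_matrix())
    @pytest.mark.parametrize("fmt", ["nexus", "phylip"])
    def test_round_trip_is_lossless(self, matrix, fmt, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("io")
        path = tmp / f"m.{fmt}"
        rp.write_matrix(matrix, path, fmt)
        back = rp.read_matrix(path, fmt, panel=matrix.panel)
        assert _state_rows(back) == _state_rows(matrix)
        assert back.taxa == matrix.taxa

    def test_minimal_phylip(self, tmp_path):
        path = tmp_path / "m.phy"
        path.write_text("2 1\nA 1\nB 0\n")
        matrix = rp.read_matrix(path, "phylip")
        assert len(matrix) == 1
        marker = matrix.markers[0]
        assert marker.state("A") is rp.MarkerState.PRESENT
        assert marker.state("B") is rp.MarkerState.ABSENT

    def test_nexus_preserves_unknown(self, tmp_path, panel):
        matrix = matrix_from_counts(rp.example_counts(), annotation_known=0)
        matrix.markers[0].states["Primates"] = rp.MarkerState.UNKNOWN
        path = tmp_path / "m.nex"
        rp.write_matrix(matrix, path, "nexus")
        back = rp.read_matrix(path, "nexus", panel=matrix.panel)
        assert back.markers[0].state("Primates") is rp.MarkerState.UNKNOWN

    def test_empty_matrix_refused(self, panel, tmp_path):
        with pytest.raises(ValueError):
            rp.write_matrix(rp.MarkerMatrix([], panel), tmp_path / "e.phy", "phylip")

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("2 x\nA 1\nB 0\n", "header"),
            ("2 1\nA 1\nA 0\n", "duplicate"),
            ("2 1\nA 2\nB 0\n", "illegal"),
            ("3 1\nA 1\nB 0\n", "taxa"),
        ],
    )
    def test_phylip_errors_name_the_line(self, tmp_path, text, fragment):
        path = tmp_path / "bad.phy"
        path.write_text(text)
        with pytest.raises(MatrixFormatError) as err:
            rp.read_matrix(path, "phylip")
        assert fragment in str(err.value).lower()


class TestFixtureBuilder:
    def test_realizes_requested_counts(self, example_matrix, example_counts):
        assert example_counts.total == 361
        assert len(example_matrix) == 361
        assert rp.annotation_concordance(example_matrix) == (299, 289)

    def test_outgroup_always_absent(self, example_matrix):
        outgroup = example_matrix.panel.outgroup[0]
        assert all(
            m.state(outgroup) is rp.MarkerState.ABSENT
            for m in example_matrix.markers
        )
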