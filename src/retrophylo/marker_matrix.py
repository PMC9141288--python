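"""Presence/absence marker matrices for retrophylogenomics.

A *marker* is a single transposed-element (TE) insertion locus scored as
present ("1"), absent ("0"), or unknown ("?") in each lineage of a study
panel.  Because TE insertions at orthologous loci are virtually free of
homoplasy, the multiset of presence patterns across four ingroup lineages
carries the phylogenetic signal: a marker present in exactly two or three
ingroup lineages (and absent in at least one) supports the clade formed by
its presence set.  For four lineages there are exactly ten such diagnostic
patterns -- six pairs and four triples.

This module holds the data model (panels, markers, matrices, pattern
counts), NEXUS/PHYLIP input and output, the diagnostic-pattern classifier,
and the summary tabulations (pattern counts, conflicting totals, and
annotation-lineage concordance).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

DEFAULT_INGROUP = ("Primates", "Dermoptera", "Scandentia", "Glires")
DEFAULT_ANNOTATION = "Lagomorpha"
DEFAULT_OUTGROUP = ("Bos_taurus",)

#: Per-pattern counts of the 361 diagnostic TE insertions recovered for the
#: four Euarchontoglires lineages, in y-vector order (see
#: :func:`y_pattern_order`).  Used as the bundled worked example.
EUARCHONTOGLIRES_Y_VECTOR = (16, 12, 9, 9, 16, 5, 13, 55, 132, 94)

#: Lagomorph annotation tallies for the worked example: number of markers
#: with a known lagomorph state, and how many of those agree with the rodent
#: (Glires) state.
EUARCHONTOGLIRES_LAGOMORPH_TALLY = (299, 289)


class MatrixFormatError(ValueError):
    """Raised when a NEXUS or PHYLIP matrix file cannot be parsed."""


class MarkerState(Enum):
    """Tri-state character of one marker in one lineage."""

    PRESENT = "1"
    ABSENT = "0"
    UNKNOWN = "?"

    @classmethod
    def from_symbol(cls, symbol: str) -> "MarkerState":
        try:
            return _SYMBOL_TABLE[symbol]
        except KeyError:
            raise MatrixFormatError(f"illegal state symbol {symbol!r}") from None

    @property
    def symbol(self) -> str:
        return self.value


_SYMBOL_TABLE = {s.value: s for s in MarkerState}


class Classification(Enum):
    """Non-pattern outcomes of :func:`classify_marker`.

    ``UNINFORMATIVE`` markers fail the pre-filter (fewer than two known
    ingroup presences, or no known ingroup absence).  ``PARTIALLY_INFORMATIVE``
    markers pass the pre-filter on their known states but carry an unknown
    ingroup state, so their presence set is not fully determined; they are
    excluded from the 10-pattern tabulation but still usable for gene-tree
    export.
    """

    UNINFORMATIVE = "uninformative"
    PARTIALLY_INFORMATIVE = "partially_informative"


@dataclass(frozen=True)
class LineagePanel:
    """Named lineages of a study: ingroup, optional annotation lineage, outgroup.

    The four (or three) ``ingroup`` lineages are the ones entering the
    pattern statistics.  The ``annotation_lineage`` (lagomorphs in the
    Euarchontoglires study design) is scored where possible but kept out of
    the four-lineage statistics; the ``outgroup`` anchors absence states.
    """

    ingroup: tuple[str, ...] = DEFAULT_INGROUP
    annotation_lineage: str | None = DEFAULT_ANNOTATION
    outgroup: tuple[str, ...] = DEFAULT_OUTGROUP

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingroup", tuple(self.ingroup))
        object.__setattr__(self, "outgroup", tuple(self.outgroup))
        names = list(self.all_lineages)
        if len(set(names)) != len(names):
            raise ValueError(f"panel lineage names are not unique: {names}")
        if not self.ingroup:
            raise ValueError("panel requires at least one ingroup lineage")
        # the 3/4-lineage and non-empty-outgroup invariants are enforced by
        # the statistics and diagnostics entry points that rely on them

    @property
    def all_lineages(self) -> tuple[str, ...]:
        extra = (self.annotation_lineage,) if self.annotation_lineage else ()
        return self.ingroup + extra + self.outgroup


@dataclass
class Marker:
    """One TE presence/absence locus scored across the panel lineages."""

    id: str
    states: dict[str, MarkerState]
    te_family: str = ""
    orientation: str = "+"

    def state(self, lineage: str) -> MarkerState:
        try:
            return self.states[lineage]
        except KeyError:
            raise KeyError(f"marker {self.id!r} has no state for lineage {lineage!r}")

    def is_informative(self, panel: LineagePanel) -> bool:
        """Pre-filter: >= 2 known ingroup presences and >= 1 known absence."""
        ingroup = [self.state(l) for l in panel.ingroup]
        return (
            sum(s is MarkerState.PRESENT for s in ingroup) >= 2
            and any(s is MarkerState.ABSENT for s in ingroup)
        )


@dataclass
class MarkerMatrix:
    """Ordered collection of markers over a shared panel."""

    markers: list[Marker]
    panel: LineagePanel

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.panel.all_lineages


def y_pattern_order(ingroup: Sequence[str] = DEFAULT_INGROUP) -> list[frozenset[str]]:
    """The ten diagnostic patterns in y-vector (hammlet upper-triangle) order.

    Index pairs (i, j) with i <= j run over the upper triangle of a 4x4
    matrix in row order -- y11, y12, y13, y14, y22, y23, y24, y33, y34, y44.
    Entry y_ij with i < j is the pattern in which lineages i and j are
    *absent* (presence set = the complementary pair); the diagonal y_ii is
    the pattern in which only lineage i is absent (presence set = the
    complementary triple).
    """
    lineages = list(ingroup)
    if len(lineages) != 4:
        raise ValueError("y-vector order is defined for 4 ingroup lineages")
    order: list[frozenset[str]] = []
    for i in range(4):
        for j in range(i, 4):
            absent = {lineages[i], lineages[j]}
            order.append(frozenset(lineages) - absent)
    return order


def diagnostic_patterns(ingroup: Sequence[str]) -> list[frozenset[str]]:
    """All pair and triple presence sets for the ingroup (10 for 4 lineages)."""
    out = [frozenset(c) for c in combinations(ingroup, 2)]
    out += [frozenset(c) for c in combinations(ingroup, len(ingroup) - 1)]
    return out


@dataclass
class PatternCounts:
    """Counts of markers per diagnostic clade pattern.

    ``pattern_order`` records the documented y-vector ordering used for
    vector-style I/O; it is configurable so alternative assignments of the
    printed conflict values can be explored.
    """

    counts: dict[frozenset[str], int]
    panel: LineagePanel
    pattern_order: list[frozenset[str]] = field(default_factory=list)
    n_uninformative: int = 0
    n_partial: int = 0

    def __post_init__(self) -> None:
        if not self.pattern_order:
            self.pattern_order = y_pattern_order(self.panel.ingroup)
        for pattern, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for pattern {sorted(pattern)}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, pattern: Iterable[str]) -> int:
        return self.counts.get(frozenset(pattern), 0)

    def y_vector(self) -> tuple[int, ...]:
        return tuple(self.counts.get(p, 0) for p in self.pattern_order)

    @classmethod
    def from_y_vector(
        cls,
        values: Sequence[int],
        panel: LineagePanel | None = None,
        pattern_order: Sequence[frozenset[str]] | None = None,
    ) -> "PatternCounts":
        panel = panel or LineagePanel()
        order = list(pattern_order) if pattern_order else y_pattern_order(panel.ingroup)
        if len(values) != len(order):
            raise ValueError(f"expected {len(order)} counts, got {len(values)}")
        return cls(dict(zip(order, map(int, values))), panel, order)

    def to_csv(self, path: str | Path) -> None:
        lines = ["pattern,count"]
        for pattern in self.pattern_order:
            lines.append(f"{'+'.join(sorted(pattern))},{self.counts.get(pattern, 0)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path, panel: LineagePanel | None = None) -> "PatternCounts":
        panel = panel or LineagePanel()
        counts: dict[frozenset[str], int] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("pattern"):
                continue
            try:
                pat, n = line.rsplit(",", 1)
                counts[frozenset(pat.split("+"))] = int(n)
            except ValueError:
                raise MatrixFormatError(f"{path}: line {ln}: malformed counts row")
        return cls(counts, panel)


# ---------------------------------------------------------------------------
# Classification and tabulation
# ---------------------------------------------------------------------------

def classify_marker(
    marker: Marker, panel: LineagePanel
) -> frozenset[str] | Classification:
    """Assign a marker to one of the ten diagnostic patterns, or declare it
    uninformative / partially informative.

    A marker contributes to the 10-pattern table only when every ingroup
    state is known and the pre-filter holds (>= 2 present, >= 1 absent); the
    presence set is then necessarily a pair or a triple.  A marker whose
    known states pass the pre-filter but that carries an unknown ingroup
    state has an undetermined presence set and is flagged
    ``PARTIALLY_INFORMATIVE`` (usable for gene-tree export only).
    """
    states = {l: marker.state(l) for l in panel.ingroup}
    present = {l for l, s in states.items() if s is MarkerState.PRESENT}
    absent = {l for l, s in states.items() if s is MarkerState.ABSENT}
    unknown = {l for l, s in states.items() if s is MarkerState.UNKNOWN}
    if len(present) < 2 or not absent:
        return Classification.UNINFORMATIVE
    if unknown:
        return Classification.PARTIALLY_INFORMATIVE
    return frozenset(present)


def tabulate(matrix: MarkerMatrix) -> PatternCounts:
    """Count markers per diagnostic pattern; unknowns and pre-filter failures
    are tallied separately (``n_partial`` / ``n_uninformative``)."""
    panel = matrix.panel
    if len(panel.ingroup) != 4:
        raise ValueError("10-pattern tabulation requires a 4-lineage ingroup")
    counts: dict[frozenset[str], int] = {p: 0 for p in y_pattern_order(panel.ingroup)}
    n_unin = n_part = 0
    for marker in matrix.markers:
        result = classify_marker(marker, panel)
        if result is Classification.UNINFORMATIVE:
            n_unin += 1
        elif result is Classification.PARTIALLY_INFORMATIVE:
            n_part += 1
        else:
            counts[result] += 1
    return PatternCounts(counts, panel, n_uninformative=n_unin, n_partial=n_part)


def conflicting_total(
    counts: PatternCounts, supported: Iterable[Iterable[str]]
) -> int:
    """Total count over all patterns *not* in ``supported``."""
    supported_sets = {frozenset(p) for p in supported}
    valid = set(counts.pattern_order) | set(counts.counts)
    for p in supported_sets:
        if p not in valid:
            raise ValueError(f"{sorted(p)} is not a diagnostic pattern of this panel")
    return sum(n for p, n in counts.counts.items() if p not in supported_sets)


def annotation_concordance(
    matrix: MarkerMatrix,
    annotation_lineage: str | None = None,
    reference_lineage: str | None = None,
) -> tuple[int, int]:
    """(n_known, n_concordant) for the annotation lineage vs a reference.

    ``n_known`` counts markers whose annotation-lineage state is not unknown;
    ``n_concordant`` counts how many of those equal the reference lineage's
    state (by default the last ingroup lineage, i.e. the rodent line).
    """
    annotation_lineage = annotation_lineage or matrix.panel.annotation_lineage
    reference_lineage = reference_lineage or matrix.panel.ingroup[-1]
    if annotation_lineage is None:
        raise ValueError("panel has no annotation lineage")
    n_known = n_conc = 0
    for marker in matrix.markers:
        a = marker.states.get(annotation_lineage, MarkerState.UNKNOWN)
        if a is MarkerState.UNKNOWN:
            continue
        n_known += 1
        if a is marker.states.get(reference_lineage):
            n_conc += 1
    return n_known, n_conc


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

def matrix_from_counts(
    counts: PatternCounts,
    annotation_known: int | None = None,
    annotation_concordant: int | None = None,
    id_prefix: str = "Euarch",
) -> MarkerMatrix:
    """Construct a marker matrix realizing a per-pattern count multiset.

    Markers are emitted grouped in the counts' pattern order, present in
    their pattern's lineages, absent elsewhere in the ingroup, and absent in
    every outgroup lineage.  When the panel has an annotation lineage,
    ``annotation_known`` markers receive a known annotation state of which
    ``annotation_concordant`` match the last ingroup lineage's state and the
    rest are flipped; the remaining markers are set to unknown.  The
    arrangement (concordant first, then conflicting, then unknown) is an
    arbitrary deterministic choice: only the tallies are data.
    """
    panel = counts.panel
    markers: list[Marker] = []
    for pattern in counts.pattern_order:
        for _ in range(counts.counts.get(pattern, 0)):
            states = {
                l: (MarkerState.PRESENT if l in pattern else MarkerState.ABSENT)
                for l in panel.ingroup
            }
            for o in panel.outgroup:
                states[o] = MarkerState.ABSENT
            markers.append(Marker(id="", states=states))
    total = len(markers)
    if panel.annotation_lineage is not None:
        known = total if annotation_known is None else annotation_known
        conc = known if annotation_concordant is None else annotation_concordant
        if not 0 <= conc <= known <= total:
            raise ValueError("need 0 <= concordant <= known <= total markers")
        reference = panel.ingroup[-1]
        for i, marker in enumerate(markers):
            ref_state = marker.states[reference]
            if i < conc:
                state = ref_state
            elif i < known:
                state = (
                    MarkerState.ABSENT
                    if ref_state is MarkerState.PRESENT
                    else MarkerState.PRESENT
                )
            else:
                state = MarkerState.UNKNOWN
            marker.states[panel.annotation_lineage] = state
    width = max(3, len(str(total)))
    for i, marker in enumerate(markers, 1):
        marker.id = f"{id_prefix}{i:0{width}d}"
    return MarkerMatrix(markers, panel)


def example_counts(panel: LineagePanel | None = None) -> PatternCounts:
    """The bundled Euarchontoglires worked-example tally (361 markers)."""
    return PatternCounts.from_y_vector(EUARCHONTOGLIRES_Y_VECTOR, panel)


def example_matrix(panel: LineagePanel | None = None) -> MarkerMatrix:
    """Marker matrix realizing the worked-example tally, with lagomorph
    annotation states matching the published concordance tallies."""
    known, conc = EUARCHONTOGLIRES_LAGOMORPH_TALLY
    return matrix_from_counts(
        example_counts(panel), annotation_known=known, annotation_concordant=conc
    )


# ---------------------------------------------------------------------------
# NEXUS / PHYLIP I/O
# ---------------------------------------------------------------------------

def _auto_ids(n: int, prefix: str = "Euarch") -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _matrix_from_rows(
    rows: dict[str, str], panel: LineagePanel | None, source: str
) -> MarkerMatrix:
    taxa = list(rows)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise MatrixFormatError(f"{source}: rows have unequal lengths {sorted(lengths)}")
    nchar = lengths.pop()
    if panel is None:
        # matrix files carry no panel metadata; assume the study layout:
        # four ingroup lineages first, an annotation lineage fifth when six
        # taxa are present, outgroup(s) last
        if len(taxa) == 6:
            panel = LineagePanel(
                ingroup=tuple(taxa[:4]),
                annotation_lineage=taxa[4],
                outgroup=(taxa[5],),
            )
        elif len(taxa) >= 5:
            panel = LineagePanel(
                ingroup=tuple(taxa[:4]),
                annotation_lineage=None,
                outgroup=tuple(taxa[4:]),
            )
        else:
            panel = LineagePanel(
                ingroup=tuple(taxa), annotation_lineage=None, outgroup=()
            )
    markers = []
    for i, mid in enumerate(_auto_ids(nchar)):
        states = {t: MarkerState.from_symbol(rows[t][i]) for t in taxa}
        markers.append(Marker(id=mid, states=states))
    return MarkerMatrix(markers, panel)


def _read_phylip(path: Path, panel: LineagePanel | None) -> MarkerMatrix:
    """Relaxed sequential PHYLIP: whitespace-delimited names of any length."""
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 2 or not all(f.isdigit() for f in header):
        raise MatrixFormatError(f"{path}: line 1: malformed PHYLIP header {lines[0]!r}")
    ntax, nchar = map(int, header)
    if len(lines) - 1 != ntax:
        raise MatrixFormatError(
            f"{path}: header declares {ntax} taxa but {len(lines) - 1} rows found"
        )
    rows: dict[str, str] = {}
    for ln, line in enumerate(lines[1:], 2):
        fields = line.split()
        name, seq = fields[0], "".join(fields[1:])
        if name in rows:
            raise MatrixFormatError(f"{path}: line {ln}: duplicate taxon {name!r}")
        if len(seq) != nchar:
            raise MatrixFormatError(
                f"{path}: line {ln}: expected {nchar} characters, got {len(seq)}"
            )
        bad = set(seq) - set("01?")
        if bad:
            raise MatrixFormatError(
                f"{path}: line {ln}: illegal symbol(s) {sorted(bad)}"
            )
        rows[name] = seq
    return _matrix_from_rows(rows, panel, str(path))


def _read_nexus(path: Path, panel: LineagePanel | None) -> MarkerMatrix:
    try:
        data = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several parse error types
        raise MatrixFormatError(f"{path}: {exc}") from exc
    rows: dict[str, str] = {}
    for taxon in data.taxon_namespace:
        label = taxon.label.replace(" ", "_")
        if label in rows:
            raise MatrixFormatError(f"{path}: duplicate taxon {label!r}")
        rows[label] = "".join(str(c) for c in data[taxon].symbols_as_list())
    for name, seq in rows.items():
        bad = set(seq) - set("01?")
        if bad:
            raise MatrixFormatError(
                f"{path}: taxon {name!r}: illegal symbol(s) {sorted(bad)}"
            )
    return _matrix_from_rows(rows, panel, str(path))


def read_matrix(
    path: str | Path,
    format: str | None = None,
    panel: LineagePanel | None = None,
) -> MarkerMatrix:
    """Read a 1/0/? marker matrix from NEXUS or PHYLIP.

    When ``panel`` is omitted, the first four taxa become the ingroup and
    the remainder the outgroup (matrix files carry no panel metadata).
    """
    path = Path(path)
    if format is None:
        head = path.read_text(errors="replace").lstrip()[:6].upper()
        format = "nexus" if head.startswith("#NEXUS") else "phylip"
    if format == "nexus":
        return _read_nexus(path, panel)
    if format == "phylip":
        return _read_phylip(path, panel)
    raise ValueError(f"unknown matrix format {format!r}")


def _state_rows(matrix: MarkerMatrix) -> dict[str, str]:
    return {
        t: "".join(m.state(t).symbol for m in matrix.markers)
        for t in matrix.taxa
    }


def write_matrix(matrix: MarkerMatrix, path: str | Path, format: str = "nexus") -> None:
    """Write a matrix as relaxed PHYLIP or as a NEXUS DATA block (datatype
    standard, symbols "01", missing "?") suitable for external network and
    Bayesian tools."""
    if not matrix.markers:
        raise ValueError("refusing to write an empty marker matrix")
    path = Path(path)
    rows = _state_rows(matrix)
    if format == "phylip":
        width = max(len(t) for t in rows) + 2
        lines = [f"{len(rows)} {len(matrix)}"]
        lines += [f"{t:<{width}}{seq}" for t, seq in rows.items()]
    elif format == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={len(rows)} NCHAR={len(matrix)};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        width = max(len(t) for t in rows) + 2
        lines += [f"        {t:<{width}}{seq}" for t, seq in rows.items()]
        lines += ["    ;", "END;"]
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    path.write_text("\n".join(lines) + "\n")
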