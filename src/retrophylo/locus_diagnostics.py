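"""Per-locus validation of candidate TE insertions.

A candidate marker is a small multiple sequence alignment of one orthologous
locus across the panel taxa, with the TE span annotated in alignment
columns.  Four diagnostic criteria decide whether the locus is a clean
presence/absence character:

1. exact presence/absence location -- gap and element boundaries agree
   across taxa to within 3 nt (measured in ungapped target-site
   coordinates, so alignment padding cannot inflate shifts);
2. the same TE family at the orthologous locus in every presence taxon;
3. the same orientation in every presence taxon;
4. absence in the outgroup.

State calling per taxon: *present* when most of the TE span is covered by
sequence; *absent* when the span is a contiguous gap whose boundaries sit
within 3 nt of the annotated insertion site and both flanks remain
alignable; everything else (N-runs, deleted flanks, large boundary shifts)
is *unknown*.  An absence gap is allowed to cover the element plus exactly
one copy of the target-site duplication (TSD): a taxon lacking the element
retains a single target-site copy, so the gap left behind is one TSD longer
than the annotated element.  Apparent boundary overhangs that match the
taxon's retained target-site copy are therefore not counted as shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .marker_matrix import MarkerState

logger = logging.getLogger(__name__)

_GAP = "-"
_LINE1_PREFIXES = ("L1", "LINE1", "LINE/L1", "LINE-1")


@dataclass(frozen=True)
class TEAnnotation:
    """One annotated TE: family, strand, span (0-based half-open columns),
    and the number of nucleotides missing from the element's 3' end."""

    family: str
    strand: str
    start: int
    end: int
    truncation_3prime: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("TE annotation requires start < end")
        if self.truncation_3prime < 0:
            raise ValueError("3' truncation must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TSD:
    """A target-site duplication: direct repeat flanking the element."""

    length: int
    left: str
    right: str


@dataclass
class LocusAlignment:
    """A per-locus MSA with one annotated TE span.

    ``te_families`` / ``te_strands`` optionally override the locus-level
    annotation per taxon (used to encode conflicting family or orientation
    calls); taxa not listed inherit ``te.family`` / ``te.strand``.
    """

    sequences: dict[str, str]
    te: TEAnnotation
    outgroup_taxa: list[str] = field(default_factory=list)
    te_families: dict[str, str] = field(default_factory=dict)
    te_strands: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
        if self.sequences and self.te.end > next(iter(lengths)):
            raise ValueError("TE span extends past the alignment length")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def family_of(self, taxon: str) -> str:
        return self.te_families.get(taxon, self.te.family)

    def strand_of(self, taxon: str) -> str:
        return self.te_strands.get(taxon, self.te.strand)


@dataclass
class DiagnosticCall:
    """Per-taxon states plus the evidence behind them.

    ``criteria_flags`` maps criterion number (1-4) to True/False, or None
    when the criterion could not be evaluated (e.g. no outgroup in the
    alignment).  ``accepted`` additionally requires the presence/absence
    pre-filter and a known-absent outgroup.
    """

    states: dict[str, MarkerState]
    shift_nt: dict[str, int] = field(default_factory=dict)
    tsds: dict[str, TSD] = field(default_factory=dict)
    criteria_flags: dict[int, bool | None] = field(default_factory=dict)
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def tsd(self) -> TSD | None:
        return next(iter(self.tsds.values()), None)


def _consensus(locus: LocusAlignment) -> str:
    """Majority base per column over all rows (gap if no row has a base)."""
    rows = list(locus.sequences.values())
    out = []
    for col in range(locus.length):
        tally: dict[str, int] = {}
        for row in rows:
            ch = row[col].upper()
            if ch in "ACGT":
                tally[ch] = tally.get(ch, 0) + 1
        out.append(max(tally, key=tally.get) if tally else _GAP)
    return "".join(out)


def _ungapped_positions(consensus: str) -> list[int]:
    """Map column -> number of consensus bases strictly before it."""
    pos, n = [], 0
    for ch in consensus:
        pos.append(n)
        if ch != _GAP:
            n += 1
    pos.append(n)
    return pos


def _identity(a: str, b: str) -> float:
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def _gap_run(row: str, start: int, end: int) -> tuple[int, int]:
    """Maximal run of gap columns containing [start, end)."""
    g0, g1 = start, end
    while g0 > 0 and row[g0 - 1] == _GAP:
        g0 -= 1
    while g1 < len(row) and row[g1] == _GAP:
        g1 += 1
    return g0, g1


def _ungapped(row: str) -> str:
    return row.replace(_GAP, "")


def _tsd_compensated(
    row: str, consensus: str, overhang_cols: tuple[int, int],
    te_start: int, te_end: int, side: str,
) -> bool:
    """Does a gap overhang correspond to the target-site duplication?

    ``overhang_cols`` is the column interval by which the taxon's gap run
    extends past the annotated span on one side.  A taxon lacking the TE
    retains a single target-site copy, so for a right overhang (the
    duplicated copy 3' of the element) the retained copy sits in the
    mirrored columns immediately 5' of the element, and vice versa.  The
    overhang is compensated when the taxon's mirrored columns match the
    consensus over the overhang at >= 75% identity with at least half the
    positions aligned.
    """
    o0, o1 = overhang_cols
    n = o1 - o0
    if side == "right":
        m0, m1 = te_start - n, te_start
    else:
        m0, m1 = te_end, te_end + n
    if m0 < 0 or m1 > len(row):
        return False
    over = consensus[o0:o1]
    mirror = row[m0:m1]
    aligned = sum(
        x.upper() in "ACGT" and y.upper() in "ACGT" for x, y in zip(over, mirror)
    )
    if aligned < max(1, n // 2):
        return False
    return _identity(over, mirror) >= 0.75


def call_states(
    locus: LocusAlignment,
    coverage_threshold: float = 0.8,
    max_shift: int = 3,
    min_flank: int = 20,
    flank_window: int = 30,
    min_flank_identity: float = 0.6,
) -> DiagnosticCall:
    """Call present/absent/unknown per taxon from the locus alignment.

    present
        at least ``coverage_threshold`` of the TE columns carry A/C/G/T.
    absent
        the TE span is a contiguous gap; after TSD compensation the gap
        boundaries sit within ``max_shift`` nt (ungapped consensus
        coordinates) of the annotated span; and both flanks show at least
        ``min_flank`` aligned bases at ``min_flank_identity`` identity to
        the consensus within ``flank_window`` columns of the gap.
    unknown
        anything else (N-runs, flank deletions, out-of-band shifts).
    """
    te = locus.te
    if te.end - te.start <= 0:
        raise ValueError("empty TE span")
    L = locus.length
    for taxon, row in locus.sequences.items():
        if len(row) != L:
            raise ValueError(f"row for {taxon!r} shorter than the alignment")
    consensus = _consensus(locus)
    upos = _ungapped_positions(consensus)
    states: dict[str, MarkerState] = {}
    shifts: dict[str, int] = {}
    for taxon, row in locus.sequences.items():
        span = row[te.start : te.end].upper()
        n_base = sum(ch in "ACGT" for ch in span)
        coverage = n_base / len(span)
        if coverage >= coverage_threshold:
            states[taxon] = MarkerState.PRESENT
            shifts[taxon] = 0
            continue
        n_gap = span.count(_GAP)
        if n_base > 0.05 * len(span) or n_gap < 0.95 * len(span):
            # neither covered nor cleanly deleted (N-runs, partial rows)
            states[taxon] = MarkerState.UNKNOWN
            continue
        g0, g1 = _gap_run(row, te.start, te.end)
        left_over = upos[te.start] - upos[g0]
        right_over = upos[g1] - upos[te.end]
        if left_over and _tsd_compensated(
            row, consensus, (g0, te.start), te.start, te.end, "left"
        ):
            left_over = 0
        if right_over and _tsd_compensated(
            row, consensus, (te.end, g1), te.start, te.end, "right"
        ):
            right_over = 0
        shift = max(left_over, right_over)
        lw0 = max(0, g0 - flank_window)
        rw1 = min(L, g1 + flank_window)
        left_bases = sum(ch.upper() in "ACGT" for ch in row[lw0:g0])
        right_bases = sum(ch.upper() in "ACGT" for ch in row[g1:rw1])
        flanks_ok = (
            left_bases >= min(min_flank, upos[g0] - upos[lw0])
            and right_bases >= min(min_flank, upos[rw1] - upos[g1])
            and left_bases >= 1
            and right_bases >= 1
            and _identity(row[lw0:g0], consensus[lw0:g0]) >= min_flank_identity
            and _identity(row[g1:rw1], consensus[g1:rw1]) >= min_flank_identity
        )
        if shift <= max_shift and flanks_ok:
            states[taxon] = MarkerState.ABSENT
            shifts[taxon] = shift
        else:
            states[taxon] = MarkerState.UNKNOWN
    return DiagnosticCall(states=states, shift_nt=shifts)


def detect_tsd(
    locus: LocusAlignment,
    taxon: str,
    min_len: int = 4,
    max_len: int = 25,
    max_mismatch: int = 1,
) -> TSD | None:
    """Longest direct repeat flanking the TE in a presence taxon.

    Compares, for lengths from ``max_len`` down to ``min_len``, the taxon's
    ungapped sequence immediately 5' of the TE start with the sequence
    immediately 3' of the TE end, accepting the first (longest) pair with at
    most ``max_mismatch`` mismatches.
    """
    row = locus.sequences[taxon]
    te = locus.te
    left = _ungapped(row[: te.start])
    right = _ungapped(row[te.end :])
    top = min(max_len, len(left), len(right))
    for L in range(top, min_len - 1, -1):
        a, b = left[-L:].upper(), right[:L].upper()
        mismatches = sum(
            x != y or x not in "ACGT" or y not in "ACGT" for x, y in zip(a, b)
        )
        if mismatches <= max_mismatch:
            return TSD(length=L, left=a, right=b)
    return None


def validate_marker(
    call: DiagnosticCall,
    locus: LocusAlignment,
    max_shift: int = 3,
    tsd_min_len: int = 4,
    tsd_max_len: int = 25,
    tsd_max_mismatch: int = 1,
) -> DiagnosticCall:
    """Apply the four diagnostic criteria to a state call and set ``accepted``.

    Also records the TSD found for each presence taxon (orthology evidence;
    absence of a detectable TSD is reported but not itself disqualifying).
    """
    states = call.states
    present = [t for t, s in states.items() if s is MarkerState.PRESENT]
    absent = [t for t, s in states.items() if s is MarkerState.ABSENT]
    call.criteria_flags[1] = all(
        call.shift_nt.get(t, 0) <= max_shift for t in present + absent
    )
    families = {locus.family_of(t) for t in present}
    call.criteria_flags[2] = len(families) <= 1
    strands = {locus.strand_of(t) for t in present}
    call.criteria_flags[3] = len(strands) <= 1
    out_states = [
        states[t] for t in locus.outgroup_taxa if t in states
    ]
    if not out_states:
        call.criteria_flags[4] = None
        call.reasons.append("no outgroup taxon present in the alignment")
    elif any(s is MarkerState.PRESENT for s in out_states):
        call.criteria_flags[4] = False
        call.reasons.append("TE present in an outgroup taxon")
    elif not any(s is MarkerState.ABSENT for s in out_states):
        call.criteria_flags[4] = False
        call.reasons.append("no outgroup taxon with a known absence state")
    else:
        call.criteria_flags[4] = True
    for taxon in present:
        tsd = detect_tsd(
            locus, taxon, min_len=tsd_min_len, max_len=tsd_max_len,
            max_mismatch=tsd_max_mismatch,
        )
        if tsd is not None:
            call.tsds[taxon] = tsd
    prefilter = len(present) >= 2 and len(absent) >= 1
    if not prefilter:
        call.reasons.append("fails presence/absence pre-filter (>=2 present, >=1 absent)")
    if call.criteria_flags[2] is False:
        call.reasons.append(f"conflicting TE families {sorted(families)}")
    if call.criteria_flags[3] is False:
        call.reasons.append(f"conflicting orientations {sorted(strands)}")
    call.accepted = prefilter and all(
        call.criteria_flags.get(i) is True for i in (1, 2, 3, 4)
    )
    return call


def line1_filter(te: TEAnnotation, max_truncation: int = 25) -> bool:
    """LINE1 3'-intactness filter: keep elements truncated by at most
    ``max_truncation`` nt at the 3' end (boundary inclusive)."""
    family = te.family.upper()
    if not any(family.startswith(p) or f"/{p}" in family for p in _LINE1_PREFIXES):
        raise ValueError(f"{te.family!r} is not a LINE1 family")
    return te.truncation_3prime <= max_truncation


# ---------------------------------------------------------------------------
# Annotation and alignment readers
# ---------------------------------------------------------------------------

def _parse_paren(tok: str, path, ln: int) -> int:
    if not (tok.startswith("(") and tok.endswith(")")):
        raise ValueError(f"{path}: line {ln}: expected parenthesized field, got {tok!r}")
    return int(tok[1:-1])


def read_te_annotations(path: str | Path, format: str = "bed") -> list[TEAnnotation]:
    """Read TE annotations from BED6 or RepeatMasker ``.out``.

    Coordinates are normalized to 0-based half-open; RepeatMasker's
    1-based-inclusive query coordinates are shifted, and orientation ``C``
    is mapped to strand ``-``.  For RepeatMasker rows the unaligned
    consensus tail (the parenthesized "left" field) is taken as the 3'
    truncation of the element.
    """
    path = Path(path)
    annotations: list[TEAnnotation] = []
    lines = path.read_text().splitlines()
    if format == "bed":
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: line {ln}: BED6 requires 6 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from None
            annotations.append(
                TEAnnotation(
                    family=fields[3], strand=fields[5], start=start, end=end
                )
            )
    elif format == "repeatmasker_out":
        for ln, line in enumerate(lines, 1):
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header / blank lines
            if len(fields) < 14:
                raise ValueError(
                    f"{path}: line {ln}: RepeatMasker rows require >= 14 fields"
                )
            try:
                qbegin, qend = int(fields[5]), int(fields[6])
                orientation = fields[8]
                family = f"{fields[9]}#{fields[10]}"
                if orientation == "C":
                    strand = "-"
                    left = _parse_paren(fields[11], path, ln)
                elif orientation == "+":
                    strand = "+"
                    left = _parse_paren(fields[13], path, ln)
                else:
                    raise ValueError(
                        f"{path}: line {ln}: orientation must be '+' or 'C'"
                    )
            except ValueError as exc:
                raise ValueError(str(exc) if str(exc).startswith(str(path)) else
                                 f"{path}: line {ln}: {exc}") from None
            annotations.append(
                TEAnnotation(
                    family=family,
                    strand=strand,
                    start=qbegin - 1,
                    end=qend,
                    truncation_3prime=left,
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return annotations


def read_locus_alignment(
    path: str | Path,
    te: TEAnnotation,
    outgroup_taxa: Sequence[str] = (),
) -> LocusAlignment:
    """Read a per-locus FASTA alignment and attach its TE annotation."""
    sequences = {
        record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    return LocusAlignment(
        sequences=sequences, te=te, outgroup_taxa=list(outgroup_taxa)
    )


def report_rows(name: str, call: DiagnosticCall) -> list[str]:
    """TSV rows (locus, taxon, state, shift, criteria flags, accepted)."""
    flags = ";".join(
        f"{i}={call.criteria_flags.get(i)}" for i in (1, 2, 3, 4)
    )
    return [
        "\t".join(
            [
                name,
                taxon,
                state.name.lower(),
                str(call.shift_nt.get(taxon, "")),
                flags,
                str(call.accepted),
            ]
        )
        for taxon, state in call.states.items()
    ]
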