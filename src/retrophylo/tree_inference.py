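"""Quartet-based species-tree inference from presence/absence markers.

Each informative marker converts to an incompletely resolved "gene tree":
its presence set forms the only non-trivial clade, with every other
known-state taxon attached to the root polytomy.  A candidate species tree
is scored by the number of (gene tree, four-taxon subset) pairs whose
induced resolved quartet it matches; with at most six taxa all unrooted
binary topologies are enumerated exhaustively, so the returned tree is the
exact quartet-score optimum (the same objective a heuristic quartet
species-tree program optimizes at scale).  Support comes from resampling
markers with replacement; internal branch lengths in coalescent units come
from the triplet discordance estimator around each branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ils_stats import TAU_CAP, estimate_internal_branch, triplet_from_counts
from .marker_matrix import (
    Classification,
    LineagePanel,
    Marker,
    MarkerMatrix,
    MarkerState,
    PatternCounts,
    classify_marker,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneTreeSet:
    """Newick gene trees (one per usable marker) over a shared taxon list."""

    trees: list[str]
    taxa: list[str]


@dataclass
class SpeciesTreeResult:
    """Best quartet topology with its score, support, and branch lengths.

    ``topology`` is rooted on the outgroup; ``bootstrap_support`` maps each
    ingroup-side clade to a recovery percentage; ``branch_lengths`` maps
    internal clades to coalescent units; ``ties`` lists co-optimal
    topologies (lexicographic tie-break, loudly reported).
    """

    topology: str
    quartet_score: int
    bootstrap_support: dict[frozenset, float] = field(default_factory=dict)
    branch_lengths: dict[frozenset, float] = field(default_factory=dict)
    ties: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Marker -> gene tree
# ---------------------------------------------------------------------------

def _marker_clade(marker: Marker, taxa: Sequence[str]) -> tuple[frozenset, frozenset] | None:
    """(presence clade, known taxa) of a marker, or None when unusable."""
    known = [t for t in taxa if marker.states.get(t, MarkerState.UNKNOWN) is not MarkerState.UNKNOWN]
    present = frozenset(
        t for t in known if marker.states[t] is MarkerState.PRESENT
    )
    if len(present) < 2:
        return None
    return present, frozenset(known)


def marker_to_genetree(
    marker: Marker, panel: LineagePanel, include_annotation: bool = False
) -> str | None:
    """Newick string for one marker: the presence set as the single resolved
    clade, other known-state taxa at the root polytomy, unknowns omitted.
    Returns None (with a log entry) for markers with < 2 known presences.
    """
    taxa = list(panel.ingroup)
    if include_annotation and panel.annotation_lineage:
        taxa.append(panel.annotation_lineage)
    taxa += list(panel.outgroup)
    cl = _marker_clade(marker, taxa)
    if cl is None:
        logger.info("marker %s skipped: fewer than 2 known presence states", marker.id)
        return None
    present, known = cl
    inside = ",".join(t for t in taxa if t in present)
    outside = ",".join(t for t in taxa if t in known - present)
    return f"(({inside}),{outside});" if outside else f"({inside});"


def gene_trees(
    matrix: MarkerMatrix, include_annotation: bool = False
) -> GeneTreeSet:
    """Gene trees for every informative or partially informative marker."""
    panel = matrix.panel
    taxa = list(panel.ingroup)
    if include_annotation and panel.annotation_lineage:
        taxa.append(panel.annotation_lineage)
    taxa += list(panel.outgroup)
    trees = []
    for marker in matrix.markers:
        newick = marker_to_genetree(marker, panel, include_annotation)
        if newick is not None:
            trees.append(newick)
    return GeneTreeSet(trees=trees, taxa=taxa)


def _parse_gene_tree(newick: str) -> tuple[frozenset, frozenset]:
    """(clade, known taxa) back out of a one-clade Newick string."""
    body = newick.strip().rstrip(";")
    if body.startswith("((") and ")" in body:
        inner, _, rest = body[2:].partition(")")
        clade = frozenset(t for t in inner.split(",") if t)
        others = frozenset(t for t in rest.strip("(),").split(",") if t)
        return clade, clade | others
    taxa = frozenset(t for t in body.strip("()").split(",") if t)
    return taxa, taxa


# ---------------------------------------------------------------------------
# Topology enumeration and quartet scoring
# ---------------------------------------------------------------------------

def _enumerate_unrooted(taxa: Sequence[str]) -> list[list[tuple]]:
    """All unrooted binary topologies on the taxon set, each as a list of
    edges between nodes (taxa are strings, internal nodes negative ints)."""
    taxa = list(taxa)
    if len(taxa) < 4:
        return [[tuple(sorted(taxa))]]
    trees = [[(taxa[0], -1), (taxa[1], -1), (taxa[2], -1)]]
    next_internal = -2
    for leaf in taxa[3:]:
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                m = next_internal
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, m), (v, m), (leaf, m)]
                grown.append(new_edges)
        trees = grown
        next_internal -= 1
    return trees


def _bipartitions(edges: list[tuple], taxa: Sequence[str]) -> list[frozenset]:
    """Non-trivial splits of an unrooted tree, each as the frozenset of the
    side not containing the first taxon."""
    adjacency: dict = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    taxa_set = set(taxa)
    anchor = taxa[0]
    splits = []
    for u, v in edges:
        # leaves reachable from v without crossing u
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in taxa_set:
                side.add(node)
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if anchor in side:
            side = taxa_set - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.append(frozenset(side))
    return sorted(set(splits), key=lambda s: sorted(s))


def _induced_pair(splits: Iterable[frozenset], taxa_set: frozenset, quartet: frozenset) -> frozenset | None:
    """How the topology resolves a quartet: the pair on one side, or None."""
    for side in splits:
        a = quartet & side
        if len(a) == 2:
            # canonical orientation: the pair containing the smallest member
            if min(quartet) in a:
                return frozenset(a)
            return frozenset(quartet - a)
    return None


def _topology_newick(splits: Sequence[frozenset], taxa: Sequence[str], outgroup: str) -> str:
    """Canonical rooted Newick (rooted on the outgroup leaf)."""
    taxa_set = frozenset(taxa)
    clades = sorted(
        {s if outgroup not in s else taxa_set - s for s in splits},
        key=len,
    )
    clades = [c for c in clades if outgroup not in c]

    def build(members: frozenset, available: list[frozenset]) -> str:
        children = []
        used: set = set()
        for clade in sorted(available, key=len, reverse=True):
            if clade < members and not clade & used:
                children.append(clade)
                used |= set(clade)
        parts = []
        for clade in children:
            sub = [c for c in available if c < clade]
            parts.append(build(clade, sub))
        parts += sorted(members - used)
        return "(" + ",".join(sorted(parts)) + ")"

    ingroup_side = taxa_set - {outgroup}
    inner = build(ingroup_side, clades)
    return f"({inner},{outgroup});"


def _score_matrix(
    topologies: list[list[frozenset]],
    taxa: Sequence[str],
    classes: list[tuple[frozenset, frozenset]],
) -> np.ndarray:
    """M[t, c] = number of resolved quartets of gene-tree class c matched by
    topology t."""
    taxa_set = frozenset(taxa)
    M = np.zeros((len(topologies), len(classes)), dtype=np.int64)
    quartet_cache: list[dict] = []
    for splits in topologies:
        cache = {}
        for quartet in map(frozenset, combinations(taxa, 4)):
            cache[quartet] = _induced_pair(splits, taxa_set, quartet)
        quartet_cache.append(cache)
    for ci, (clade, known) in enumerate(classes):
        usable = known & taxa_set
        resolved = []
        inside = sorted(clade & usable)
        outside = sorted(usable - clade)
        for pair_in in combinations(inside, 2):
            for pair_out in combinations(outside, 2):
                quartet = frozenset(pair_in + pair_out)
                pair = frozenset(pair_in)
                if min(quartet) not in pair:
                    pair = frozenset(pair_out)
                resolved.append((quartet, pair))
        for ti in range(len(topologies)):
            cache = quartet_cache[ti]
            M[ti, ci] = sum(
                1 for quartet, pair in resolved if cache[quartet] == pair
            )
    return M


def _marker_classes(
    matrix: MarkerMatrix, taxa: Sequence[str]
) -> tuple[list[tuple[frozenset, frozenset]], np.ndarray, list[int]]:
    """Distinct (clade, known) classes, their counts, and per-marker class
    indices (markers without a usable clade are dropped)."""
    classes: dict[tuple[frozenset, frozenset], int] = {}
    assignment = []
    for marker in matrix.markers:
        cl = _marker_clade(marker, taxa)
        if cl is None:
            continue
        idx = classes.setdefault(cl, len(classes))
        assignment.append(idx)
    counts = np.zeros(len(classes), dtype=np.int64)
    for idx in assignment:
        counts[idx] += 1
    return list(classes), counts, assignment


def quartet_species_tree(
    genetrees: GeneTreeSet, outgroup: str | None = None
) -> SpeciesTreeResult:
    """Exhaustive quartet-score species tree for <= 6 taxa.

    Ties are broken lexicographically on the rooted Newick string and
    reported in ``ties``.
    """
    if not genetrees.trees:
        raise ValueError("no gene trees to score")
    taxa = list(genetrees.taxa)
    if len(taxa) > 6:
        raise ValueError("exhaustive enumeration is limited to 6 taxa")
    outgroup = outgroup or taxa[-1]
    class_counts: dict[tuple[frozenset, frozenset], int] = {}
    for newick in genetrees.trees:
        cl = _parse_gene_tree(newick)
        class_counts[cl] = class_counts.get(cl, 0) + 1
    classes = list(class_counts)
    counts = np.array([class_counts[c] for c in classes], dtype=np.int64)
    topo_splits = [
        _bipartitions(edges, taxa) for edges in _enumerate_unrooted(taxa)
    ]
    M = _score_matrix(topo_splits, taxa, classes)
    scores = M @ counts
    best_score = int(scores.max())
    winners = [i for i, s in enumerate(scores) if s == best_score]
    newicks = sorted(
        (_topology_newick(topo_splits[i], taxa, outgroup), i) for i in winners
    )
    best_newick, best_idx = newicks[0]
    ties = [nw for nw, _ in newicks[1:]]
    if ties:
        logger.warning(
            "quartet species tree has %d co-optimal topologies; "
            "lexicographic tie-break selected %s", len(ties) + 1, best_newick,
        )
    return SpeciesTreeResult(
        topology=best_newick, quartet_score=best_score, ties=ties
    )


def bootstrap_support(
    matrix: MarkerMatrix,
    replicates: int = 1000,
    seed: int = 0,
    include_annotation: bool = False,
    outgroup: str | None = None,
) -> dict[frozenset, float]:
    """Marker-resampling bootstrap: per-clade recovery percentage over the
    best quartet topology of each pseudoreplicate.  Bit-reproducible for a
    fixed seed."""
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    panel = matrix.panel
    taxa = list(panel.ingroup)
    if include_annotation and panel.annotation_lineage:
        taxa.append(panel.annotation_lineage)
    taxa += list(panel.outgroup)
    outgroup = outgroup or (panel.outgroup[0] if panel.outgroup else taxa[-1])
    classes, counts, assignment = _marker_classes(matrix, taxa)
    if not assignment:
        raise ValueError("no usable markers for bootstrap")
    topo_edges = _enumerate_unrooted(taxa)
    topo_splits = [_bipartitions(edges, taxa) for edges in topo_edges]
    M = _score_matrix(topo_splits, taxa, classes)
    taxa_set = frozenset(taxa)
    rooted_clades = [
        [s if outgroup not in s else taxa_set - s for s in splits]
        for splits in topo_splits
    ]
    newicks = [_topology_newick(s, taxa, outgroup) for s in topo_splits]
    n_markers = len(assignment)
    probs = counts / counts.sum()
    rng = np.random.default_rng(int(seed) % 2**31)
    clade_hits: dict[frozenset, int] = {}
    for _ in range(replicates):
        resampled = rng.multinomial(n_markers, probs)
        scores = M @ resampled
        best_score = scores.max()
        winners = [i for i, s in enumerate(scores) if s == best_score]
        best = min(winners, key=lambda i: newicks[i])
        for clade in rooted_clades[best]:
            clade_hits[clade] = clade_hits.get(clade, 0) + 1
    return {
        clade: 100.0 * hits / replicates for clade, hits in clade_hits.items()
    }


def annotate_branch_lengths(
    result: SpeciesTreeResult, counts: PatternCounts, cap: float = TAU_CAP
) -> SpeciesTreeResult:
    """Attach coalescent-unit lengths to the internal ingroup branches.

    Each branch whose child clade is a pair or triple of ingroup lineages is
    measured by the triplet discordance estimator on the pattern counts
    around that branch; branches touching the outgroup carry no marker
    signal here and are left unannotated.
    """
    panel = counts.panel
    ingroup = set(panel.ingroup)
    clades = _clades_from_newick(result.topology)
    lengths: dict[frozenset, float] = {}
    for clade in clades:
        members = clade & ingroup
        if members != clade or len(clade) not in (2, 3):
            continue
        parents = [c for c in clades if clade < c] + [frozenset(panel.ingroup)]
        parent = min(parents, key=len)
        sibling_set = parent - clade
        if len(sibling_set) != 1:
            continue
        triplet = triplet_from_counts(counts, clade, next(iter(sibling_set)))
        if triplet.total == 0:
            continue
        lengths[clade] = estimate_internal_branch(triplet, cap=cap)
    result.branch_lengths = lengths
    return result


def _clades_from_newick(newick: str) -> list[frozenset]:
    """Non-trivial clades of a rooted Newick string (no branch lengths)."""
    stack: list[list] = [[]]
    token = ""
    clades: list[frozenset] = []
    for ch in newick:
        if ch == "(":
            stack.append([])
        elif ch in ",)":
            if token:
                stack[-1].append(token)
                token = ""
            if ch == ")":
                members = frozenset(stack.pop())
                if len(members) >= 2:
                    clades.append(members)
                stack[-1].append(members)
        elif ch in "; \n":
            continue
        else:
            token += ch
    # flatten nested frozensets
    def flatten(x):
        if isinstance(x, frozenset):
            out = set()
            for item in x:
                out |= flatten(item)
            return out
        return {x}

    return sorted({frozenset(flatten(c)) for c in clades}, key=lambda c: (len(c), sorted(c)))


def to_newick(result: SpeciesTreeResult) -> str:
    """Annotated Newick: bootstrap percentages as internal node labels and
    coalescent-unit branch lengths where estimated."""
    base = result.topology

    def annotate(members: frozenset) -> str:
        label = ""
        if members in result.bootstrap_support:
            label = f"{result.bootstrap_support[members]:g}"
        length = result.branch_lengths.get(members)
        if length is not None:
            label += f":{length:.4f}"
        return label

    # re-build by parsing the canonical topology
    def build(newick: str) -> str:
        stack: list[list] = [[]]
        token = ""
        out_stack: list[list[str]] = [[]]
        for ch in newick:
            if ch == "(":
                stack.append([])
                out_stack.append([])
            elif ch in ",)":
                if token:
                    stack[-1].append(token)
                    out_stack[-1].append(token)
                    token = ""
                if ch == ")":
                    members = stack.pop()
                    flat = set()
                    for m in members:
                        flat |= m if isinstance(m, set) else {m}
                    parts = out_stack.pop()
                    rendered = "(" + ",".join(parts) + ")" + annotate(frozenset(flat))
                    stack[-1].append(flat)
                    out_stack[-1].append(rendered)
            elif ch in "; \n":
                continue
            else:
                token += ch
        return out_stack[0][0] + ";"

    return build(base)
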