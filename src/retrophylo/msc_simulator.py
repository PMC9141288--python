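"""Multispecies-coalescent simulator for TE presence/absence markers.

Generative model
----------------
A four-lineage species tree ``(((a,b):tau1, c):tau2, d):root_stem`` is
traversed backwards in time.  Within every ancestral population, sampled
lineages coalesce with the Kingman rate k(k-1)/2 per coalescent unit;
lineages that have not coalesced by the end of a branch are passed to the
parent population (incomplete lineage sorting).  A TE marker is an insertion
placed uniformly at random on the gene-tree branch segments lying *within*
the ancestral populations (insertion opportunity proportional to branch
length, optionally reweighted per species-tree branch); the marker is
present in exactly the extant lineages descending from the insertion point.
Insertions above the stem of the full ingroup would also be carried by the
outgroup, so insertable length stops at the top of the root stem.  Markers
whose presence set has fewer than two or all four lineages fail the
diagnostic pre-filter and are rejected and redrawn, so the emitted matrix
contains only pair and triple patterns (before optional unknown-masking).

Markers are modeled as single-copy, homoplasy-free characters: no parallel
insertion and no precise excision.  The only noise channel is the optional
``missing_rate`` masking of states to "?".

The module also plants synthetic per-locus alignments (TE insertion with
target-site duplication, optional boundary shift, i.i.d. substitutions in
flanks) for exercising the locus diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from numba import njit

from .locus_diagnostics import LocusAlignment, TEAnnotation
from .marker_matrix import (
    LineagePanel,
    Marker,
    MarkerMatrix,
    MarkerState,
)

CATERPILLAR = 0
BALANCED = 1

_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.int64)


@dataclass(frozen=True)
class SimulationConfig:
    """Species-tree branch lengths (coalescent units) and marker parameters.

    tau1
        Stem of the (a,b) cherry -- Primatomorpha in the default panel.
    tau2
        Stem of the (a,b,c) triple -- Euarchonta in the default panel.
    root_stem
        Stem of the full ingroup; the duration between the root speciation
        and the split from the outgroup, i.e. the deepest ancestral
        population that can still receive outgroup-absent insertions.
    branch_weights
        Relative insertion rates on the three ancestral species-tree
        branches (cherry stem, triple stem, root stem).
    missing_rate
        Probability that a simulated state is masked to unknown ("?").
    """

    tau1: float = 0.5
    tau2: float = 1.0
    root_stem: float = 1.0
    n_markers: int = 1000
    branch_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tau1, self.tau2, self.root_stem) < 0:
            raise ValueError("branch lengths must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "branch_weights" in raw:
            raw["branch_weights"] = tuple(raw["branch_weights"])
        return cls(**raw)


@dataclass(frozen=True)
class LocusSimConfig:
    """Parameters of a planted per-locus alignment (lengths in nt)."""

    flank_length: int = 150
    te_length: int = 300
    tsd_length: int = 12
    shift_nt: int = 0
    substitution_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.flank_length, self.te_length, self.tsd_length) <= 0:
            raise ValueError("flank, TE and TSD lengths must be positive")
        if self.shift_nt < 0:
            raise ValueError("shift_nt must be >= 0")


# ---------------------------------------------------------------------------
# numba kernels: ancestral-branch segment bookkeeping
# ---------------------------------------------------------------------------
#
# Lineages are 4-bit masks (role a=1, b=2, c=4, d=8).  Each kernel simulates
# gene trees population by population and records, for every gene-tree
# branch segment inside an ancestral population, the (weighted) segment
# length keyed by the segment's descendant mask.


@njit(cache=True)
def _coalesce_pop(masks, k, duration, weight, seg_mask, seg_len, nseg):
    """Kingman coalescent within one population of finite duration.

    Records one weighted segment per surviving lineage per inter-event
    interval.  Returns the surviving lineage count and segment count.
    """
    t = 0.0
    while k >= 2:
        rate = 0.5 * k * (k - 1)
        dt = np.random.exponential(1.0 / rate)
        if t + dt >= duration:
            break
        for i in range(k):
            seg_mask[nseg] = masks[i]
            seg_len[nseg] = weight * dt
            nseg += 1
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        lo = min(i, j)
        hi = max(i, j)
        masks[lo] = masks[i] | masks[j]
        masks[hi] = masks[k - 1]
        k -= 1
        t += dt
    rem = duration - t
    if rem > 0.0:
        for i in range(k):
            seg_mask[nseg] = masks[i]
            seg_len[nseg] = weight * rem
            nseg += 1
    return k, nseg


@njit(cache=True)
def _replicate_segments(shape, tau1, tau2, taur, w1, w2, wr, masks, seg_mask, seg_len):
    """Segments of one gene-tree replicate inside the ancestral populations."""
    nseg = 0
    if shape == CATERPILLAR:
        masks[0] = 1
        masks[1] = 2
        k, nseg = _coalesce_pop(masks, 2, tau1, w1, seg_mask, seg_len, nseg)
        masks[k] = 4
        k, nseg = _coalesce_pop(masks, k + 1, tau2, w2, seg_mask, seg_len, nseg)
        masks[k] = 8
        k, nseg = _coalesce_pop(masks, k + 1, taur, wr, seg_mask, seg_len, nseg)
    else:
        masks[0] = 1
        masks[1] = 2
        ka, nseg = _coalesce_pop(masks, 2, tau1, w1, seg_mask, seg_len, nseg)
        masks[ka] = 4
        masks[ka + 1] = 8
        kb, nseg = _coalesce_pop(masks[ka:], 2, tau2, w2, seg_mask, seg_len, nseg)
        k, nseg = _coalesce_pop(masks, ka + kb, taur, wr, seg_mask, seg_len, nseg)
    return nseg


@njit(cache=True)
def _pattern_lengths(shape, tau1, tau2, taur, w1, w2, wr, n_mc, seed):
    """MC-averaged probability mass per descendant mask.

    One insertion is placed uniformly on each replicate gene tree's
    insertable (ancestral-population) branch length, so the mass of mask
    ``m`` is the mean of the per-replicate weighted length fraction of
    segments with that descendant mask -- the Rao-Blackwellized form of the
    marker sampler's per-tree uniform draw.
    """
    np.random.seed(seed)
    acc = np.zeros(16)
    masks = np.empty(8, np.int64)
    seg_mask = np.empty(64, np.int64)
    seg_len = np.empty(64)
    for _ in range(n_mc):
        nseg = _replicate_segments(
            shape, tau1, tau2, taur, w1, w2, wr, masks, seg_mask, seg_len
        )
        total = 0.0
        for s in range(nseg):
            total += seg_len[s]
        if total <= 0.0:
            continue
        for s in range(nseg):
            acc[seg_mask[s]] += seg_len[s] / total
    return acc / n_mc


@njit(cache=True)
def _sample_marker_masks(shape, tau1, tau2, taur, w1, w2, wr, n_markers, seed):
    """Draw one informative presence mask per marker by rejection.

    Returns an array of masks, or a first element of -1 when the species
    tree has zero insertable ancestral branch length.
    """
    np.random.seed(seed)
    out = np.empty(n_markers, np.int64)
    masks = np.empty(8, np.int64)
    seg_mask = np.empty(64, np.int64)
    seg_len = np.empty(64)
    popcount = np.array([0, 1, 1, 2, 1, 2, 2, 3, 1, 2, 2, 3, 2, 3, 3, 4])
    for m in range(n_markers):
        accepted = False
        for _ in range(100000):
            nseg = _replicate_segments(
                shape, tau1, tau2, taur, w1, w2, wr, masks, seg_mask, seg_len
            )
            total = 0.0
            for s in range(nseg):
                total += seg_len[s]
            if total <= 0.0:
                out[0] = -1
                return out
            u = np.random.random() * total
            acc = 0.0
            chosen = 0
            for s in range(nseg):
                acc += seg_len[s]
                if u < acc:
                    chosen = seg_mask[s]
                    break
            pc = popcount[chosen]
            if pc == 2 or pc == 3:
                out[m] = chosen
                accepted = True
                break
        if not accepted:
            out[0] = -1
            return out
    return out


def ancestral_pattern_lengths(
    tau1: float,
    tau2: float,
    root_stem: float,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
    n_mc: int = 200_000,
    seed: int = 0,
    shape: int = CATERPILLAR,
) -> np.ndarray:
    """MC-averaged insertable branch length per presence mask (length 16)."""
    w1, w2, wr = weights
    return _pattern_lengths(
        shape,
        float(tau1),
        float(tau2),
        float(root_stem),
        float(w1),
        float(w2),
        float(wr),
        int(n_mc),
        int(seed) % 2**31,
    )


# ---------------------------------------------------------------------------
# Gene trees (object form)
# ---------------------------------------------------------------------------

def _py_coalesce(lineages, duration, t0, rng):
    """Python-level Kingman step used when an explicit gene tree is wanted.

    ``lineages`` is a list of (node, height) pairs; returns survivors and
    the population's exit time.
    """
    t = t0
    end = t0 + duration
    while len(lineages) >= 2:
        k = len(lineages)
        dt = rng.exponential(1.0 / (0.5 * k * (k - 1)))
        if t + dt >= end:
            break
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = t - hi
        nj.edge.length = t - hj
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append((parent, t))
    return lineages, end


def simulate_gene_tree(
    config: SimulationConfig,
    panel: LineagePanel | None = None,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """One rooted gene tree (branch lengths in coalescent units) under the
    MSC on ``(((a,b):tau1, c):tau2, d):root_stem``.

    Lineages not coalesced by the top of the root stem finish coalescing in
    the unbounded ancestral population above it.
    """
    panel = panel or LineagePanel()
    a, b, c, d = panel.ingroup
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tns = dendropy.TaxonNamespace([a, b, c, d])

    def leaf(name):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(name)
        return (node, 0.0)

    lineages, t = _py_coalesce([leaf(a), leaf(b)], config.tau1, 0.0, rng)
    lineages.append(leaf(c))
    lineages, t = _py_coalesce(lineages, config.tau2, t, rng)
    lineages.append(leaf(d))
    lineages, t = _py_coalesce(lineages, config.root_stem, t, rng)
    lineages, _ = _py_coalesce(lineages, np.inf, t, rng)
    root, _height = lineages[0]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def triplet_resolution(tree: dendropy.Tree, triplet: Sequence[str]) -> frozenset[str]:
    """Which pair of ``triplet`` coalesces first in a rooted gene tree."""
    taxa = set(triplet)
    best_pair, best_depth = None, None
    for node in tree.preorder_node_iter():
        leaves = {
            l.taxon.label for l in node.leaf_iter()
        } & taxa
        if len(leaves) == 2:
            depth = node.level()
            if best_depth is None or depth > best_depth:
                best_pair, best_depth = frozenset(leaves), depth
    if best_pair is None:
        raise ValueError("triplet does not resolve in this gene tree")
    return best_pair


# ---------------------------------------------------------------------------
# Marker matrices
# ---------------------------------------------------------------------------

def simulate_markers(
    config: SimulationConfig, panel: LineagePanel | None = None
) -> MarkerMatrix:
    """Simulate an informative marker matrix under the MSC insertion model.

    Outgroup lineages are always absent (all insertions postdate the
    outgroup split); the annotation lineage, if any, is not simulated.
    Deterministic for a given config.
    """
    panel = panel or LineagePanel(annotation_lineage=None)
    w1, w2, wr = config.branch_weights
    seed = int(config.seed) % 2**31
    masks = _sample_marker_masks(
        CATERPILLAR,
        float(config.tau1),
        float(config.tau2),
        float(config.root_stem),
        float(w1),
        float(w2),
        float(wr),
        int(config.n_markers),
        seed,
    )
    if masks[0] < 0:
        raise ValueError(
            "zero insertable ancestral branch length (all stem lengths or "
            "weights are zero)"
        )
    rng = np.random.default_rng((seed * 2654435761 + 101) % 2**31)
    ingroup = panel.ingroup
    markers = []
    width = max(3, len(str(config.n_markers)))
    for i, mask in enumerate(masks, 1):
        states = {}
        for bit, lineage in enumerate(ingroup):
            present = bool(mask >> bit & 1)
            states[lineage] = MarkerState.PRESENT if present else MarkerState.ABSENT
        for o in panel.outgroup:
            states[o] = MarkerState.ABSENT
        if panel.annotation_lineage:
            states[panel.annotation_lineage] = MarkerState.UNKNOWN
        if config.missing_rate > 0:
            for lineage in ingroup:
                if rng.random() < config.missing_rate:
                    states[lineage] = MarkerState.UNKNOWN
        markers.append(
            Marker(id=f"sim{i:0{width}d}", states=states, te_family="SIM#LTR/SIM")
        )
    return MarkerMatrix(markers, panel)


# ---------------------------------------------------------------------------
# Planted locus alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def simulate_locus(
    config: LocusSimConfig,
    plan: Mapping[str, bool],
    shifted_taxa: Mapping[str, int] | Sequence[str] | None = None,
    outgroup_taxa: Sequence[str] = (),
    te_family: str = "MER57F#LTR/ERV1",
) -> tuple[LocusAlignment, dict[str, dict]]:
    """Generate one gapped locus alignment with a planted TE insertion.

    ``plan`` maps taxon -> planted presence.  Present taxa carry the TE
    flanked by a duplicated target site (TSD); absent taxa retain a single
    target-site copy and an alignment gap over the TE plus the second TSD
    copy.  ``shifted_taxa`` maps absent taxa to a planted boundary shift in
    nt (the gap boundary cuts that far into the retained target site).  All
    taxa share ancestral flanks subject to i.i.d. substitutions.  Returns
    the alignment plus a machine-readable truth record.
    """
    rng = np.random.default_rng(int(config.seed) % 2**31)
    if shifted_taxa is None:
        shifted_taxa = {}
    elif not isinstance(shifted_taxa, Mapping):
        shifted_taxa = {t: config.shift_nt for t in shifted_taxa}
    else:
        shifted_taxa = dict(shifted_taxa)
    fl = "".join(rng.choice(_BASES, config.flank_length))
    tsd = "".join(rng.choice(_BASES, config.tsd_length))
    te = "".join(rng.choice(_BASES, config.te_length))
    fr = "".join(rng.choice(_BASES, config.flank_length))
    rate = config.substitution_rate
    rows: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for taxon in plan:
        present = plan[taxon]
        m_fl = _mutate(fl, rate, rng)
        m_tsd = _mutate(tsd, rate, rng)
        m_fr = _mutate(fr, rate, rng)
        if present:
            row = m_fl + m_tsd + _mutate(te, rate, rng) + _mutate(tsd, rate, rng) + m_fr
            truth[taxon] = {"state": "present", "shift": 0}
        else:
            shift = int(shifted_taxa.get(taxon, 0))
            if shift > config.tsd_length:
                raise ValueError("planted shift cannot exceed the TSD length")
            kept = m_tsd[: config.tsd_length - shift] if shift else m_tsd
            gap = "-" * (config.te_length + config.tsd_length + shift)
            row = m_fl + kept + gap + m_fr
            truth[taxon] = {"state": "absent", "shift": shift}
        rows[taxon] = row
    te_start = config.flank_length + config.tsd_length
    annotation = TEAnnotation(
        family=te_family,
        strand="+",
        start=te_start,
        end=te_start + config.te_length,
        truncation_3prime=0,
    )
    locus = LocusAlignment(
        sequences=rows, te=annotation, outgroup_taxa=list(outgroup_taxa)
    )
    return locus, truth


def write_locus_fasta(locus: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in locus.sequences.items():
            fh.write(f">{taxon}\n{row}\n")


def write_locus_bed(locus: LocusAlignment, name: str, path: str | Path) -> None:
    te = locus.te
    Path(path).write_text(
        f"{name}\t{te.start}\t{te.end}\t{te.family}\t0\t{te.strand}\n"
    )
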