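"""Statistical tests on diagnostic TE pattern counts.

Three-lineage test
------------------
For a lineage triplet, markers split into ``n1`` supporting the candidate
clade and ``n2``, ``n3`` supporting the two alternative resolutions.  Under
a hard polytomy the three resolutions are equiprobable, so the
tree-versus-polytomy p-value is the exact binomial tail
``P(X >= n1), X ~ Binomial(n1+n2+n3, 1/3)``.  Under pure incomplete lineage
sorting (ILS) the two conflicting classes are symmetric, so the
hybridization/introgression check is a two-sided exact binomial test of
``n2`` against ``n3`` with success probability 1/2.

Four-lineage test
-----------------
The ten pattern counts of a four-lineage panel are modeled as a multinomial
whose cell probabilities come from the multispecies-coalescent insertion
model (see ``msc_simulator``): for each of the fifteen rooted four-taxon
topologies, the log-likelihood is maximized over the two internal branch
lengths (tau1, tau2, coalescent units) on a Monte-Carlo probability grid
with local refinement.  Tree-versus-polytomy is a likelihood-ratio test of
the winning topology against the same topology with its cherry stem
constrained to zero (tau1 = 0).  Because tau1 = 0 lies on the boundary, the
LRT null is the 50:50 mixture of a point mass at zero and chi-square(1);
and because a polytomy admits three competing resolutions of the tested
node, the mixture p-value is Bonferroni-corrected by that factor of three,
which keeps the test's size at its nominal level under topology selection.
Hybridization is screened by two-sided binomial tests between
mirror-symmetric conflict patterns (patterns that swap the two cherry
lineages), Holm-corrected.

Branch lengths
--------------
The internal branch above a resolved triplet is estimated from the
gene-tree discordance relation ``(n2+n3)/N = (2/3) exp(-tau)``:
``tau_hat = max(0, -ln(1.5 (n2+n3)/N))``, capped at a documented maximum
when no conflicting markers are observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .marker_matrix import LineagePanel, PatternCounts
from .msc_simulator import BALANCED, CATERPILLAR, ancestral_pattern_lengths

logger = logging.getLogger(__name__)

#: Branch-length cap (coalescent units) reported when no conflicting
#: markers are observed and the point estimate diverges.
TAU_CAP = 10.0

#: tau grid used for the four-lineage likelihood surfaces: dense where the
#: pattern probabilities change fastest, sparser in the asymptotic regime.
TAU_GRID = np.concatenate(
    [
        np.arange(0.0, 1.0, 0.05),
        np.arange(1.0, 2.0, 0.1),
        np.arange(2.0, 3.5, 0.25),
        np.arange(3.5, 5.01, 0.5),
    ]
)

_GRID_CACHE: dict[tuple, np.ndarray] = {}


@dataclass(frozen=True)
class TripletCounts:
    """Marker counts for one lineage triplet: candidate clade vs the two
    alternative resolutions."""

    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


@dataclass
class KkscResult:
    p_topology: float
    p_hybridization: float
    significant_tree: bool
    alpha: float


@dataclass
class FourLinResult:
    best_topology: str
    tau1_hat: float
    tau2_hat: float
    lrt_stat: float
    p_polytomy: float
    symmetry_pvalues: dict[tuple[frozenset, frozenset], float]
    symmetry_pvalues_holm: dict[tuple[frozenset, frozenset], float]
    log_likelihood: float
    topology_logliks: dict[str, float] = field(default_factory=dict)


def kksc_test(counts: TripletCounts, alpha: float = 0.01) -> KkscResult:
    """Exact three-lineage tree-vs-polytomy and hybridization test."""
    N = counts.total
    if N < 1:
        raise ValueError("no informative markers for this triplet")
    p_topology = float(stats.binom.sf(counts.n1 - 1, N, 1.0 / 3.0))
    n_conflict = counts.n2 + counts.n3
    if n_conflict == 0:
        p_hyb = 1.0
    else:
        p_hyb = float(
            stats.binomtest(counts.n2, n_conflict, 0.5, alternative="two-sided").pvalue
        )
    return KkscResult(
        p_topology=min(p_topology, 1.0),
        p_hybridization=min(p_hyb, 1.0),
        significant_tree=p_topology < alpha,
        alpha=alpha,
    )


def estimate_internal_branch(counts: TripletCounts, cap: float = TAU_CAP) -> float:
    """Coalescent-unit length of the internal branch above a triplet.

    Inverts the triplet discordance relation; returns ``cap`` when no
    conflicting markers are observed (the point estimate is infinite) and
    0 at or beyond the star-tree limit (conflict fraction >= 2/3).
    """
    N = counts.total
    if N < 1:
        raise ValueError("no informative markers for this triplet")
    conflict = counts.n2 + counts.n3
    if conflict == 0:
        return cap
    return float(min(cap, max(0.0, -np.log(1.5 * conflict / N))))


# ---------------------------------------------------------------------------
# Pattern probabilities under the MSC insertion model
# ---------------------------------------------------------------------------

_INFORMATIVE_MASKS = [m for m in range(16) if bin(m).count("1") in (2, 3)]


def _mask_to_pattern(mask: int, lineages: Sequence[str]) -> frozenset[str]:
    return frozenset(l for i, l in enumerate(lineages) if mask >> i & 1)


def pattern_probs(
    tau1: float,
    tau2: float,
    root_stem: float = 1.0,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
    n_mc: int = 200_000,
    seed: int = 0,
    panel: LineagePanel | None = None,
    shape: int = CATERPILLAR,
) -> dict[frozenset[str], float]:
    """Monte-Carlo pattern probabilities, conditioned on informative patterns.

    Lineage roles follow the panel's ingroup order: for the caterpillar
    shape the species tree is ``(((a,b):tau1, c):tau2, d):root_stem``; for
    the balanced shape ``((a,b):tau1, (c,d):tau2):root_stem``.
    Deterministic given ``seed``.
    """
    panel = panel or LineagePanel()
    lengths = ancestral_pattern_lengths(
        tau1, tau2, root_stem, weights=weights, n_mc=n_mc, seed=seed, shape=shape
    )
    informative = lengths[_INFORMATIVE_MASKS]
    total = informative.sum()
    if total <= 0:
        raise ValueError("no informative insertable branch length at these taus")
    probs = informative / total
    return {
        _mask_to_pattern(m, panel.ingroup): float(p)
        for m, p in zip(_INFORMATIVE_MASKS, probs)
    }


def _prob_grid(
    shape: int, root_stem: float, weights: tuple, n_mc: int, seed: int
) -> np.ndarray:
    """Cached grid P[i, j, k]: probability of informative role-pattern k at
    (tau1, tau2) = (TAU_GRID[i], TAU_GRID[j])."""
    key = (shape, float(root_stem), tuple(weights), int(n_mc), int(seed))
    if key not in _GRID_CACHE:
        logger.info("building 4-LIN probability grid (shape=%s)...", shape)
        n = len(TAU_GRID)
        grid = np.empty((n, n, len(_INFORMATIVE_MASKS)))
        for i, t1 in enumerate(TAU_GRID):
            for j, t2 in enumerate(TAU_GRID):
                lengths = ancestral_pattern_lengths(
                    t1, t2, root_stem, weights=weights, n_mc=n_mc,
                    seed=seed, shape=shape,
                )
                informative = lengths[_INFORMATIVE_MASKS]
                grid[i, j] = informative / informative.sum()
        _GRID_CACHE[key] = grid
    return _GRID_CACHE[key]


# ---------------------------------------------------------------------------
# Rooted four-taxon topologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Topology:
    """One rooted four-lineage topology with its role assignment.

    ``roles`` orders the lineages as (a, b, c, d) of the shape's species
    tree; for caterpillars (a,b) is the cherry and d the outermost lineage,
    for balanced trees (a,b) and (c,d) are the two cherries.
    """

    shape: int
    roles: tuple[str, str, str, str]

    @property
    def label(self) -> str:
        a, b, c, d = self.roles
        a, b = sorted((a, b))
        if self.shape == CATERPILLAR:
            return f"((({a},{b}),{c}),{d})"
        c, d = sorted((c, d))
        return f"(({a},{b}),({c},{d}))"

    def role_pattern(self, mask: int) -> frozenset[str]:
        return frozenset(l for i, l in enumerate(self.roles) if mask >> i & 1)

    def cherries(self) -> list[tuple[str, str]]:
        out = [(self.roles[0], self.roles[1])]
        if self.shape == BALANCED:
            out.append((self.roles[2], self.roles[3]))
        return out


def enumerate_topologies(lineages: Sequence[str]) -> list[_Topology]:
    """All 15 rooted binary topologies on four lineages (12 caterpillars
    plus 3 balanced)."""
    if len(lineages) != 4:
        raise ValueError("topology enumeration requires exactly 4 lineages")
    out: list[_Topology] = []
    lset = list(lineages)
    for pair in combinations(lset, 2):
        rest = [l for l in lset if l not in pair]
        for c in rest:
            d = next(l for l in rest if l != c)
            out.append(_Topology(CATERPILLAR, (pair[0], pair[1], c, d)))
    seen = set()
    for pair in combinations(lset, 2):
        rest = tuple(l for l in lset if l not in pair)
        key = frozenset([frozenset(pair), frozenset(rest)])
        if key not in seen:
            seen.add(key)
            out.append(_Topology(BALANCED, (pair[0], pair[1], rest[0], rest[1])))
    return out


def _count_vector(counts: PatternCounts, topology: _Topology) -> np.ndarray:
    return np.array(
        [
            counts.counts.get(topology.role_pattern(m), 0)
            for m in _INFORMATIVE_MASKS
        ],
        dtype=float,
    )


def _loglik_on_grid(grid: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(grid > 0, np.log(np.maximum(grid, 1e-300)), -np.inf) * n
    return np.where(np.isnan(ll), -np.inf, ll).sum(axis=-1)


def _interp_probs(grid: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Bilinear interpolation of the probability grid at (t1, t2)."""
    taus = TAU_GRID

    def locate(t):
        t = float(np.clip(t, taus[0], taus[-1]))
        i = int(np.searchsorted(taus, t, side="right") - 1)
        i = min(i, len(taus) - 2)
        f = (t - taus[i]) / (taus[i + 1] - taus[i])
        return i, f

    i, fi = locate(t1)
    j, fj = locate(t2)
    p = (
        grid[i, j] * (1 - fi) * (1 - fj)
        + grid[i + 1, j] * fi * (1 - fj)
        + grid[i, j + 1] * (1 - fi) * fj
        + grid[i + 1, j + 1] * fi * fj
    )
    return p


def _refine(grid: np.ndarray, n: np.ndarray, t1_0: float, t2_0: float,
            fix_t1: bool = False) -> tuple[float, float, float]:
    """Local continuous refinement of the log-likelihood on the interpolated
    surface, starting from a grid argmax."""
    lo, hi = TAU_GRID[0], TAU_GRID[-1]

    def negll(theta):
        t1 = 0.0 if fix_t1 else theta[0]
        t2 = theta[-1]
        p = _interp_probs(grid, t1, t2)
        if np.any((p <= 0) & (n > 0)):
            return 1e12
        with np.errstate(divide="ignore"):
            return -float(np.sum(np.where(n > 0, n * np.log(np.maximum(p, 1e-300)), 0.0)))

    x0 = [t2_0] if fix_t1 else [t1_0, t2_0]
    bounds = [(lo, hi)] * len(x0)
    res = optimize.minimize(negll, x0, method="Powell", bounds=bounds)
    t1 = 0.0 if fix_t1 else float(res.x[0])
    t2 = float(res.x[-1])
    return -float(res.fun), t1, t2


def _symmetry_pairs(topology: _Topology) -> list[tuple[frozenset, frozenset]]:
    """Unordered pattern pairs related by swapping the leaves of a cherry;
    equiprobable under pure ILS, skewed under hybridization."""
    lineages = set(topology.roles)
    patterns = [frozenset(c) for k in (2, 3) for c in combinations(sorted(lineages), k)]
    pairs: list[tuple[frozenset, frozenset]] = []
    seen = set()
    for x, y in topology.cherries():
        swap = {x: y, y: x}
        for p in patterns:
            q = frozenset(swap.get(l, l) for l in p)
            if q == p:
                continue
            key = frozenset([p, q])
            if key in seen:
                continue
            seen.add(key)
            pairs.append(tuple(sorted((p, q), key=lambda s: sorted(s))))
    return pairs


def _holm(pvalues: Sequence[float]) -> list[float]:
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def fourlin_test(
    counts: PatternCounts,
    alpha: float = 0.05,
    root_stem: float = 1.0,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_mc_grid: int = 100_000,
    seed: int = 0,
) -> FourLinResult:
    """Four-lineage maximum-likelihood topology fit with a boundary LRT of
    tree versus polytomy and binomial symmetry checks for hybridization.

    ``n_mc_grid`` / ``seed`` control the cached Monte-Carlo probability
    surfaces; results are deterministic given both.
    """
    panel = counts.panel
    if len(panel.ingroup) != 4:
        raise ValueError("the four-lineage test requires a 4-lineage ingroup")
    if counts.total < 10:
        raise ValueError("need at least 10 informative markers")
    grids = {
        shape: _prob_grid(shape, root_stem, tuple(weights), n_mc_grid, seed)
        for shape in (CATERPILLAR, BALANCED)
    }
    topologies = enumerate_topologies(panel.ingroup)
    grid_best: dict[_Topology, tuple[float, int, int]] = {}
    for topo in topologies:
        n = _count_vector(counts, topo)
        ll = _loglik_on_grid(grids[topo.shape], n)
        idx = np.unravel_index(np.argmax(ll), ll.shape)
        grid_best[topo] = (float(ll[idx]), int(idx[0]), int(idx[1]))
    top_ll = max(v[0] for v in grid_best.values())
    refined: dict[_Topology, tuple[float, float, float]] = {}
    for topo, (ll0, i, j) in grid_best.items():
        if ll0 >= top_ll - 3.0 and np.isfinite(ll0):
            n = _count_vector(counts, topo)
            refined[topo] = _refine(
                grids[topo.shape], n, TAU_GRID[i], TAU_GRID[j]
            )
    best = max(refined, key=lambda t: refined[t][0])
    ll_best, tau1_hat, tau2_hat = refined[best]
    n = _count_vector(counts, best)
    null_grid_ll = _loglik_on_grid(grids[best.shape], n)[0, :]
    j0 = int(np.argmax(null_grid_ll))
    ll_null, _, _ = _refine(grids[best.shape], n, 0.0, TAU_GRID[j0], fix_t1=True)
    lrt = max(0.0, 2.0 * (ll_best - ll_null))
    if lrt <= 0:
        p_poly = 1.0
    else:
        # 50:50 boundary mixture, Bonferroni over the three resolutions of
        # the tested node
        p_poly = float(min(1.0, 3.0 * 0.5 * stats.chi2.sf(lrt, df=1)))
    sym_pairs = _symmetry_pairs(best)
    raw = []
    for p, q in sym_pairs:
        a = counts.counts.get(p, 0)
        b = counts.counts.get(q, 0)
        if a + b == 0:
            raw.append(1.0)
        else:
            raw.append(float(stats.binomtest(a, a + b, 0.5).pvalue))
    holm = _holm(raw)
    return FourLinResult(
        best_topology=best.label,
        tau1_hat=tau1_hat,
        tau2_hat=tau2_hat,
        lrt_stat=lrt,
        p_polytomy=p_poly,
        symmetry_pvalues=dict(zip(sym_pairs, raw)),
        symmetry_pvalues_holm=dict(zip(sym_pairs, holm)),
        log_likelihood=ll_best,
        topology_logliks={t.label: v[0] for t, v in grid_best.items()},
    )


# ---------------------------------------------------------------------------
# Triplet extraction from four-lineage counts
# ---------------------------------------------------------------------------

def triplet_from_counts(
    counts: PatternCounts, clade: Iterable[str], sibling: str
) -> TripletCounts:
    """Triplet counts around an internal branch.

    The branch's child clade splits into subclades X and Y (for a pair,
    its two lineages; for a triple, the nested pair and the remaining
    lineage) and ``sibling`` is the lineage group Z immediately outside the
    branch; the triplet counts are the patterns X+Y (= the clade), X+Z and
    Y+Z with each group collapsed to its taxon set.
    """
    clade = frozenset(clade)
    panel_ingroup = set(counts.panel.ingroup)
    if not clade <= panel_ingroup:
        raise ValueError("clade must be a subset of the panel ingroup")
    if len(clade) == 2:
        x, y = (frozenset([l]) for l in sorted(clade))
    elif len(clade) == 3:
        # X = the nested pair in panel order, Y = the remaining lineage
        ordered = sorted(clade, key=counts.panel.ingroup.index)
        x, y = frozenset(ordered[:2]), frozenset(ordered[2:])
    else:
        raise ValueError("triplet extraction requires a pair or triple clade")
    z = frozenset([sibling])
    return TripletCounts(
        n1=counts.counts.get(x | y, 0),
        n2=counts.counts.get(x | z, 0),
        n3=counts.counts.get(y | z, 0),
    )
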