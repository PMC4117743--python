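"""Conformational structure analysis: clustering, compactness, substructures.

Domain-like "highly interactive substructures" are contiguous stretches of
chain that fold into a compact blob: a maximal bead interval whose minimal
enclosing sphere has diameter at most 800 nm and whose DNA content exceeds
400 kbp (>= 134 beads at 3 kbp/bead).  Substructures sharing many proximal
persistence units with other substructures of the same chain are classed
*interactive* (> 20 % of units proximal), the rest *independent*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .model import Conformation, ModelParameters, WeightedEnsemble
from .observables import ContactProfile, contact_probability
from .scaling import ALPHA_FIT_RANGE, ScalingFit, alpha_from_contacts

__all__ = [
    "Substructure",
    "ClusterAssignment",
    "minimal_enclosing_sphere",
    "distance_matrix",
    "cluster_ensemble",
    "classify_compactness",
    "compactness_thresholds",
    "find_substructures",
    "classify_substructures",
    "substructure_summary",
]


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl, move-to-front)

def _ball_of(support: List[np.ndarray]) -> Tuple[np.ndarray, float]:
    """Smallest ball with the 0..4 support points on its boundary."""
    m = len(support)
    if m == 0:
        return np.zeros(3), -1.0
    if m == 1:
        return support[0].copy(), 0.0
    p0 = support[0]
    rows = [2.0 * (p - p0) for p in support[1:]]
    rhs = [float(p @ p - p0 @ p0) for p in support[1:]]
    if m == 2:
        c = 0.5 * (support[0] + support[1])
        return c, float(np.linalg.norm(support[0] - c))
    if m == 3:
        # constrain the centre to the plane of the three points
        normal = np.cross(support[1] - p0, support[2] - p0)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:  # collinear: ball of the two farthest points
            pts = np.array(support)
            d = squareform(pdist(pts))
            i, j = np.unravel_index(np.argmax(d), d.shape)
            return _ball_of([pts[i], pts[j]])
        rows.append(normal)
        rhs.append(float(normal @ p0))
    A = np.array(rows)
    b = np.array(rhs)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        c, *_ = np.linalg.lstsq(A, b, rcond=None)
    return c, float(np.linalg.norm(support[0] - c))


def minimal_enclosing_sphere(points: np.ndarray,
                             seed: int = 0) -> Tuple[np.ndarray, float]:
    """Exact smallest ball containing all points (Welzl's algorithm).

    Returns ``(center, radius)``.  Expected linear time after the initial
    random shuffle; exact up to floating-point round-off.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        raise ValueError("need at least one point")
    order = np.random.default_rng(seed).permutation(n)
    pts = pts[order]

    def welzl(i: int, support: List[np.ndarray]) -> Tuple[np.ndarray, float]:
        if i == 0 or len(support) == 4:
            return _ball_of(support)
        c, r = welzl(i - 1, support)
        p = pts[i - 1]
        if np.linalg.norm(p - c) <= r + 1e-9:
            return c, r
        return welzl(i - 1, support + [p])

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        c, r = welzl(n, [])
    finally:
        sys.setrecursionlimit(old)
    return c, r


# ---------------------------------------------------------------------------
# distance matrices and clustering

def distance_matrix(conf: Conformation, resolution: str = "units") -> np.ndarray:
    """Symmetric pairwise Euclidean distance matrix of one conformation,
    between unit-boundary beads (default) or all beads."""
    if resolution == "units":
        x = conf.unit_coordinates
    elif resolution == "beads":
        x = conf.coordinates
    else:
        raise ValueError(f"unknown resolution {resolution!r}")
    return squareform(pdist(x))


@dataclass
class ClusterAssignment:
    """Hierarchical clustering of an ensemble by conformational similarity."""

    labels: np.ndarray            # per-chain cluster index, 1..n_clusters
    n_clusters: int
    linkage_record: np.ndarray    # scipy linkage matrix
    per_cluster_alpha: Dict[int, ScalingFit] = field(default_factory=dict)


def cluster_ensemble(ensemble: WeightedEnsemble,
                     n_clusters: int = 20,
                     unit_stride: Optional[int] = None,
                     fit_range: Tuple[float, float] = ALPHA_FIT_RANGE,
                     r_c: Optional[float] = None,
                     fit_alpha: bool = True) -> ClusterAssignment:
    """Cluster chains by the RMS difference of their unit-level distance
    matrices (average-linkage hierarchical clustering cut at ``n_clusters``)
    and fit a per-cluster contact exponent alpha.

    ``unit_stride`` subsamples the units entering the dissimilarity (the
    matrices are smooth on the unit scale, and the full N=1000 matrices of
    a large ensemble do not fit in memory); default keeps ~150 units.
    """
    n_chains = len(ensemble)
    if n_clusters > n_chains:
        raise ValueError("n_clusters cannot exceed the number of chains")
    n = ensemble.n_units
    if unit_stride is None:
        unit_stride = max(1, n // 150)
    stack = ensemble.unit_coordinate_stack()[:, ::unit_stride, :]
    mats = np.stack([squareform(pdist(x)) for x in stack])
    flat = mats.reshape(n_chains, -1)
    # RMS difference of distance matrices == Euclidean distance / sqrt(m)
    dis = pdist(flat) / math.sqrt(flat.shape[1])
    link = hierarchy.linkage(dis, method="average")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")

    per_alpha: Dict[int, ScalingFit] = {}
    if fit_alpha:
        s_grid = np.unique(np.round(np.logspace(
            math.log10(2), math.log10(min(n - 1, 2 * fit_range[1])), 40)).astype(int))
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) < 2:
                continue
            sub = ensemble.subset(idx)
            prof = contact_probability([sub], s_grid, r_c=r_c)
            ok = prof.Pc_values > 0
            try:
                per_alpha[int(lab)] = alpha_from_contacts(
                    ContactProfile(prof.s_values[ok], prof.Pc_values[ok],
                                   prof.contact_radius_nm,
                                   prof.source_conditions,
                                   prof.n_effective[ok]),
                    fit_range)
            except ValueError:
                continue
    return ClusterAssignment(labels=labels, n_clusters=int(n_clusters),
                             linkage_record=link, per_cluster_alpha=per_alpha)


# ---------------------------------------------------------------------------
# compactness

def _rod_rg(n_beads: int, params: ModelParameters) -> float:
    """Radius of gyration of a fully extended (rod) chain of n beads."""
    length = (n_beads - 1) * params.bead_diameter_nm
    return length / math.sqrt(12.0)


def compactness_thresholds(ensembles: Sequence[WeightedEnsemble],
                           quantiles: Tuple[float, float] = (0.2, 0.8),
                           ) -> Tuple[float, float]:
    """Absolute rod-normalized-Rg cutoffs from the pooled (weighted)
    distribution over several conditions; chains below the lower cutoff are
    compact, above the upper cutoff open."""
    ratios, weights = [], []
    for e in ensembles:
        w = e.normalized_weights()
        for conf, wi in zip(e, w):
            ratios.append(conf.radius_of_gyration() / _rod_rg(conf.n_beads, e.params))
            weights.append(wi / len(ensembles))
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    cw = np.cumsum(np.asarray(weights)[order])
    cw /= cw[-1]
    lo = float(r[np.searchsorted(cw, quantiles[0])])
    hi = float(r[min(np.searchsorted(cw, quantiles[1]), len(r) - 1)])
    return lo, hi


def classify_compactness(ensemble: WeightedEnsemble,
                         thresholds: Tuple[float, float]) -> Dict[str, float]:
    """Weight-weighted fractions of compact / intermediate / open chains.

    A chain's compactness score is its radius of gyration divided by the
    rod (fully extended) bound; ``thresholds = (lo, hi)`` are absolute
    cutoffs on that ratio (see :func:`compactness_thresholds`).
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must satisfy lo < hi")
    w = ensemble.normalized_weights()
    frac = {"compact": 0.0, "intermediate": 0.0, "open": 0.0}
    for conf, wi in zip(ensemble, w):
        ratio = conf.radius_of_gyration() / _rod_rg(conf.n_beads, ensemble.params)
        if ratio < lo:
            frac["compact"] += wi
        elif ratio > hi:
            frac["open"] += wi
        else:
            frac["intermediate"] += wi
    return frac


# ---------------------------------------------------------------------------
# substructures

@dataclass
class Substructure:
    """A contiguous bead interval folded into a compact blob."""

    bead_interval: Tuple[int, int]      # half-open [start, end)
    dna_kbp: float
    enclosing_diameter_nm: float
    category: Optional[str] = None      # "interactive" | "independent"
    interaction_fraction: float = math.nan
    strictly_isolated: Optional[bool] = None  # no unit proximal at all

    @property
    def n_beads(self) -> int:
        return self.bead_interval[1] - self.bead_interval[0]


def _reduced_points(coords: np.ndarray, a: int, e: int, bpu: int) -> np.ndarray:
    """Point set whose enclosing ball encloses every bead of [a, e).

    Interpolated beads are convex combinations of the unit-boundary beads
    flanking them, so boundary beads inside the interval plus the two
    interval end beads suffice.
    """
    first_b = ((a + bpu - 1) // bpu) * bpu
    bounds = np.arange(first_b, e, bpu)
    idx = np.unique(np.concatenate([[a], bounds, [e - 1]]))
    return coords[idx]


def _exact_mes(coords: np.ndarray, a: int, e: int, bpu: int,
               ) -> Tuple[np.ndarray, float]:
    """Exact MES of beads [a, e), via the reduced point set and its hull."""
    pts = _reduced_points(coords, a, e, bpu)
    if len(pts) > 16:
        from scipy.spatial import ConvexHull, QhullError
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat/collinear): Welzl handles it directly
    return minimal_enclosing_sphere(pts)


def find_substructures(conf: Conformation,
                       sphere_diameter_nm: float = 800.0,
                       min_kbp: float = 400.0,
                       params: Optional[ModelParameters] = None,
                       ) -> List[Substructure]:
    """Detect domain-like substructures by a sliding-sphere scan.

    For every persistence unit, a sphere of diameter ``sphere_diameter_nm``
    is centred on its boundary bead and the contiguous run of units whose
    boundary beads stay inside that sphere is measured.  A unit qualifies
    when its run carries more than ``min_kbp`` of DNA; the fragments
    (runs) of qualifying units are merged into maximal non-overlapping
    substructure intervals.  The reported enclosing diameter is the exact
    minimal enclosing sphere of the merged interval's beads, which can
    slightly exceed the detection stencil when several fragments merge.
    """
    params = params or conf.params
    coords = conf.coordinates
    bpu = params.beads_per_unit
    U = conf.unit_coordinates
    n = len(U)
    radius = sphere_diameter_nm / 2.0
    min_units = min_kbp * 1e3 / (params.bp_per_bead * bpu)

    d2 = ((U[:, None, :] - U[None, :, :]) ** 2).sum(axis=2)
    inside = d2 <= radius * radius
    frag_lo = np.empty(n, dtype=int)
    frag_hi = np.empty(n, dtype=int)
    qual = np.zeros(n, dtype=bool)
    for i in range(n):
        row = inside[i]
        lo = i
        while lo - 1 >= 0 and row[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < n and row[hi + 1]:
            hi += 1
        frag_lo[i], frag_hi[i] = lo, hi
        qual[i] = (hi - lo + 1) > min_units

    # merge overlapping fragments of qualifying units (unit intervals,
    # half-open)
    merged: List[List[int]] = []
    for i in np.flatnonzero(qual):
        a, b = int(frag_lo[i]), int(frag_hi[i]) + 1
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    out: List[Substructure] = []
    for a_u, b_u in merged:
        # a run of units owns its beads_per_unit beads each, so the bead
        # interval extends through the last unit's interpolated beads
        a = a_u * bpu
        e = min(b_u * bpu, conf.n_beads)
        _, r = _exact_mes(coords, a, e, bpu)
        out.append(Substructure(
            bead_interval=(a, e),
            dna_kbp=(e - a) * params.bp_per_bead / 1e3,
            enclosing_diameter_nm=2.0 * r))
    return out


def classify_substructures(substructures: Sequence[Substructure],
                           conf: Conformation,
                           r_c: Optional[float] = None,
                           params: Optional[ModelParameters] = None,
                           interactive_fraction: float = 0.20,
                           ) -> List[Substructure]:
    """Classify substructures as interactive or independent.

    A persistence-unit block of a substructure is *proximal* when any of
    its beads lies within ``r_c`` of any bead of a different substructure
    of the same chain; the substructure is interactive when more than
    ``interactive_fraction`` of its unit blocks are proximal.
    ``strictly_isolated`` additionally reports the stricter reading under
    which no unit at all is proximal.
    """
    params = params or conf.params
    if r_c is None:
        r_c = params.contact_radius_nm
    bpu = params.beads_per_unit
    subs = list(substructures)
    coords = conf.coordinates
    trees = [cKDTree(coords[s.bead_interval[0]:s.bead_interval[1]]) for s in subs]
    out = []
    for i, s in enumerate(subs):
        a, e = s.bead_interval
        beads = np.arange(a, e)
        blocks = beads // bpu
        uniq = np.unique(blocks)
        if len(subs) == 1:
            out.append(replace(s, category="independent",
                               interaction_fraction=0.0, strictly_isolated=True))
            continue
        prox_bead = np.zeros(len(beads), dtype=bool)
        for j, t in enumerate(trees):
            if j == i:
                continue
            hits = t.query_ball_point(coords[a:e], r=r_c)
            prox_bead |= np.array([len(h) > 0 for h in hits])
        prox_units = np.unique(blocks[prox_bead])
        frac = len(prox_units) / len(uniq)
        out.append(replace(
            s,
            category="interactive" if frac > interactive_fraction else "independent",
            interaction_fraction=float(frac),
            strictly_isolated=bool(len(prox_units) == 0)))
    return out


def substructure_summary(ensemble: WeightedEnsemble,
                         sphere_diameter_nm: float = 800.0,
                         min_kbp: float = 400.0,
                         r_c: Optional[float] = None) -> Dict[str, float]:
    """Weighted per-chain substructure statistics over an ensemble.

    Returns the mean substructure count per chain, the fraction of chain
    (beads) they cover, and the fraction of substructures classified
    interactive (weighting each chain's substructures by the chain weight).
    """
    w = ensemble.normalized_weights()
    counts = np.zeros(len(w))
    coverage = np.zeros(len(w))
    inter_w = 0.0
    total_w = 0.0
    for i, conf in enumerate(ensemble):
        subs = find_substructures(conf, sphere_diameter_nm, min_kbp,
                                  ensemble.params)
        subs = classify_substructures(subs, conf, r_c, ensemble.params)
        counts[i] = len(subs)
        coverage[i] = sum(s.n_beads for s in subs) / conf.n_beads
        for s in subs:
            total_w += w[i]
            if s.category == "interactive":
                inter_w += w[i]
    return {
        "mean_substructures_per_chain": float(w @ counts),
        "mean_coverage_fraction": float(w @ coverage),
        "interactive_fraction": float(inter_w / total_w) if total_w > 0 else math.nan,
    }
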