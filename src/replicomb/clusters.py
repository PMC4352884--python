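"""Cluster calling and cluster-level analyses.

A replication cluster is a maximal chain of at least ``min_n`` called
origins in which every adjacent spacing is at most ``d_max`` kb (defaults 5
and 40).  The maximal-chain definition makes calling deterministic, unique,
idempotent, and monotone in both parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import OriginCall, bin_by_extent
from .molecule import Molecule


@dataclass(frozen=True)
class ClusterParams:
    d_max_kb: float = 40.0
    min_n: int = 5

    def __post_init__(self):
        if self.d_max_kb <= 0:
            raise ValueError("d_max must be positive")
        if self.min_n < 2:
            raise ValueError("min_n must be at least 2")


@dataclass(frozen=True)
class ClusterCall:
    molecule_id: str
    positions_kb: Tuple[float, ...]
    start_kb: float
    end_kb: float

    @property
    def n_origins(self) -> int:
        return len(self.positions_kb)

    @property
    def size_kb(self) -> float:
        """Span from first to last member origin."""
        return self.end_kb - self.start_kb

    @property
    def mean_internal_iod_kb(self) -> float:
        return float(np.mean(np.diff(self.positions_kb)))


def _origins_by_molecule(origins: Iterable[OriginCall]) -> Dict[str, np.ndarray]:
    by: Dict[str, List[float]] = {}
    for o in origins:
        by.setdefault(o.molecule_id, []).append(o.position_kb)
    return {k: np.sort(np.array(v)) for k, v in by.items()}


def call_clusters(
    origins: Iterable[OriginCall], params: ClusterParams = ClusterParams()
) -> List[ClusterCall]:
    """Left-to-right sweep chaining origins while the gap is <= d_max
    (inclusive bound); chains with >= min_n origins are emitted."""
    out: List[ClusterCall] = []
    for mid, pos in _origins_by_molecule(origins).items():
        if len(pos) == 0:
            continue
        chain = [pos[0]]
        for p in pos[1:]:
            if p - chain[-1] <= params.d_max_kb:
                chain.append(p)
            else:
                if len(chain) >= params.min_n:
                    out.append(
                        ClusterCall(mid, tuple(chain), chain[0], chain[-1])
                    )
                chain = [p]
        if len(chain) >= params.min_n:
            out.append(ClusterCall(mid, tuple(chain), chain[0], chain[-1]))
    return out


@dataclass
class TransitionScan:
    min_n_values: np.ndarray
    clusters_per_genome: np.ndarray
    elbow: int
    improvement_ratio: float  # one-line SSE / best two-segment SSE


def _fit_line(x, y):
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(resid @ resid)


def _two_segment_elbow(xs: np.ndarray, ys: np.ndarray) -> Tuple[int, float]:
    """Boundary of the steep-then-shallow two-segment fit.

    The elbow is the break minimising total squared error among breaks whose
    first segment descends more steeply than the second (the curve's initial
    steeply descending segment); without such a break the unconstrained
    minimiser is returned.  The fit-improvement ratio (one-line SSE over best
    two-segment SSE) is computed on ``log1p`` counts, where the geometric
    decay of spurious chains on unstructured data is a single straight line.
    """

    def scan(values, constrain):
        best_b, best = None, np.inf
        for k in range(1, len(xs) - 1):
            s1, e1 = _fit_line(xs[: k + 1], values[: k + 1])
            s2, e2 = _fit_line(xs[k:], values[k:])
            if constrain and s1 >= s2:
                continue
            if e1 + e2 < best:
                best, best_b = e1 + e2, int(xs[k])
        return best_b, best

    b, _ = scan(ys, constrain=True)
    if b is None:
        b, _ = scan(ys, constrain=False)
    logy = np.log1p(ys)
    _, one = _fit_line(xs, logy)
    _, best_log = scan(logy, constrain=False)
    ratio = one / best_log if best_log > 0 else np.inf
    return b, ratio


def transition_point_scan(
    origins: Iterable[OriginCall],
    molecules: Sequence[Molecule],
    genome_kb: float,
    d_max_kb: float = 40.0,
    min_n_range: Sequence[int] = tuple(range(2, 11)),
) -> TransitionScan:
    """Clusters per genome as ``min_n`` varies, with an elbow estimate.

    Counts are scaled by genome length over total analyzed molecule length.
    The elbow is the boundary of the two-segment least-squares fit that
    minimises total squared error; ``improvement_ratio`` (one-line SSE over
    two-segment SSE) is near 1 when the curve decays smoothly with no elbow.
    """
    origins = list(origins)
    analyzed_kb = sum(m.length_kb for m in molecules)
    scale = genome_kb / analyzed_kb
    counts = []
    for mn in min_n_range:
        calls = call_clusters(origins, ClusterParams(d_max_kb, mn))
        counts.append(len(calls) * scale)
    xs = np.asarray(list(min_n_range), dtype=float)
    ys = np.asarray(counts, dtype=float)
    elbow, ratio = _two_segment_elbow(xs, ys)
    return TransitionScan(xs.astype(int), ys, elbow, ratio)


@dataclass
class ClusterStatistics:
    n_clusters: int
    within_iods_kb: np.ndarray
    mean_within_iod_kb: float
    median_within_iod_kb: float
    sizes_kb: np.ndarray
    origins_per_cluster_mean: float
    clusters_per_genome: float
    clusters_per_genome_by_bin: Dict[str, float]
    fraction_origins_in_clusters: float
    between_iods_kb: np.ndarray
    mean_between_iod_kb: float
    foci_table: Optional[pd.DataFrame] = None

    def size_histogram(self, bin_kb: float = 2.0) -> pd.DataFrame:
        if len(self.sizes_kb) == 0:
            return pd.DataFrame({"size_kb": [], "count": []})
        edges = np.arange(0, self.sizes_kb.max() + 2 * bin_kb, bin_kb)
        counts, _ = np.histogram(self.sizes_kb, bins=edges)
        return pd.DataFrame({"size_kb": edges[:-1], "count": counts})


def cluster_statistics(
    clusters: Sequence[ClusterCall],
    origins: Iterable[OriginCall],
    molecules: Sequence[Molecule],
    genome_kb: float,
    focus_counts: Optional[Dict[str, float]] = None,
) -> ClusterStatistics:
    """Summary of cluster calls: within/between IODs, sizes, genome scaling.

    ``focus_counts`` (extent-bin label -> observed focus count per nucleus)
    adds a correspondence table comparing genome-scaled cluster counts with
    the supplied focus counts.
    """
    origins = list(origins)
    analyzed_kb = sum(m.length_kb for m in molecules)
    scale = genome_kb / analyzed_kb if analyzed_kb else float("nan")

    within = (
        np.concatenate([np.diff(c.positions_kb) for c in clusters])
        if clusters
        else np.array([])
    )
    sizes = np.array([c.size_kb for c in clusters])
    n_in = sum(c.n_origins for c in clusters)
    n_all = len(origins)

    # between-cluster IODs: adjacent-origin gaps with neither endpoint in a cluster
    member: Dict[str, set] = {}
    for c in clusters:
        member.setdefault(c.molecule_id, set()).update(c.positions_kb)
    between = []
    for mid, pos in _origins_by_molecule(origins).items():
        mem = member.get(mid, set())
        for a, b in zip(pos[:-1], pos[1:]):
            if a not in mem and b not in mem:
                between.append(b - a)
    between = np.array(between)

    # per-extent-bin genome scaling
    by_bin: Dict[str, float] = {}
    frac = {m.molecule_id: m.replicated_fraction for m in molecules}
    for label in set(bin_by_extent(f) for f in frac.values()):
        mols = [m for m in molecules if bin_by_extent(frac[m.molecule_id]) == label]
        kb = sum(m.length_kb for m in mols)
        ids = {m.molecule_id for m in mols}
        n_cl = sum(1 for c in clusters if c.molecule_id in ids)
        by_bin[label] = n_cl * genome_kb / kb if kb else float("nan")

    foci = None
    if focus_counts is not None:
        rows = [
            (label, by_bin.get(label, float("nan")), n_foci)
            for label, n_foci in focus_counts.items()
        ]
        foci = pd.DataFrame(rows, columns=["extent_bin", "clusters_per_genome", "foci_per_nucleus"])

    return ClusterStatistics(
        n_clusters=len(clusters),
        within_iods_kb=within,
        mean_within_iod_kb=float(within.mean()) if len(within) else float("nan"),
        median_within_iod_kb=float(np.median(within)) if len(within) else float("nan"),
        sizes_kb=sizes,
        origins_per_cluster_mean=(
            float(np.mean([c.n_origins for c in clusters])) if clusters else float("nan")
        ),
        clusters_per_genome=len(clusters) * scale,
        clusters_per_genome_by_bin=by_bin,
        fraction_origins_in_clusters=(n_in / n_all if n_all else 0.0),
        between_iods_kb=between,
        mean_between_iod_kb=float(between.mean()) if len(between) else float("nan"),
        foci_table=foci,
    )


@dataclass
class ExtensionReport:
    n_new_origins: int
    n_adjacent: int
    expected_adjacent: float
    enrichment: float
    p_value: float


def cluster_extension(
    clusters: Sequence[ClusterCall],
    new_origins: Iterable[OriginCall],
    molecules: Sequence[Molecule],
    adjacency_kb: float = 40.0,
    n_mc: int = 1000,
    seed: int = 0,
) -> ExtensionReport:
    """Enrichment of newly fired (chase-only) origins next to existing clusters.

    Counts new origins within ``adjacency_kb`` of a cluster span and compares
    with the expectation under uniform placement of the same number of
    origins on each molecule's unreplicated DNA (Monte Carlo).
    """
    new_by = _origins_by_molecule(new_origins)
    mols = {m.molecule_id: m for m in molecules}
    spans: Dict[str, List[Tuple[float, float]]] = {}
    for c in clusters:
        spans.setdefault(c.molecule_id, []).append((c.start_kb, c.end_kb))

    def adjacent(pos: np.ndarray, sp: List[Tuple[float, float]]) -> int:
        if len(sp) == 0 or len(pos) == 0:
            return 0
        hit = np.zeros(len(pos), dtype=bool)
        for a, b in sp:
            hit |= (pos >= a - adjacency_kb) & (pos <= b + adjacency_kb)
        return int(hit.sum())

    n_new = sum(len(p) for p in new_by.values())
    obs = sum(adjacent(pos, spans.get(mid, [])) for mid, pos in new_by.items())
    if n_new == 0:
        return ExtensionReport(0, 0, 0.0, float("nan"), 1.0)

    # unreplicated gaps per molecule for the null placement
    rng = np.random.default_rng(seed)
    gaps: Dict[str, np.ndarray] = {}
    for mid in new_by:
        m = mols[mid]
        ivs = m.labeled_intervals()
        edges = [0.0] + [x for iv in ivs for x in iv] + [m.length_kb]
        g = np.array(edges).reshape(-1, 2)
        g = g[g[:, 1] - g[:, 0] > 0]
        gaps[mid] = g

    null = np.zeros(n_mc)
    for b in range(n_mc):
        tot = 0
        for mid, pos in new_by.items():
            g = gaps[mid]
            if len(g) == 0:
                continue
            w = g[:, 1] - g[:, 0]
            u = rng.uniform(0, w.sum(), size=len(pos))
            edges = np.concatenate([[0], np.cumsum(w)])
            j = np.searchsorted(edges, u, side="right") - 1
            sim = g[j, 0] + (u - edges[j])
            tot += adjacent(sim, spans.get(mid, []))
        null[b] = tot
    expected = float(null.mean())
    p = float((1 + np.sum(null >= obs)) / (n_mc + 1))
    enr = obs / expected if expected > 0 else float("inf")
    return ExtensionReport(n_new, obs, expected, enr, p)


@dataclass
class PositionalOverlap:
    position_kb: float
    n_covering: int
    n_overlapping: int
    fraction: float
    null_fraction: float
    p_value: float


def positional_overlap(
    molecules: Sequence[Molecule],
    clusters: Sequence[ClusterCall],
    reference_positions_kb: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> List[PositionalOverlap]:
    """Fraction of aligned molecules with a cluster overlapping each position.

    Molecules must be aligned (chromosomal ``offset_kb`` set); cluster spans
    are lifted to the genome frame and a molecule counts as overlapping a
    reference position if any of its cluster spans intersects it
    (any-intersection rule).  The permutation null re-places each molecule's
    cluster spans uniformly within the molecule.
    """
    rng = np.random.default_rng(seed)
    aligned = [m for m in molecules if m.offset_kb is not None]
    spans_by: Dict[str, List[Tuple[float, float]]] = {}
    for c in clusters:
        spans_by.setdefault(c.molecule_id, []).append((c.start_kb, c.end_kb))

    def genome_spans(m: Molecule, spans) -> List[Tuple[float, float]]:
        return [(m.offset_kb + a, m.offset_kb + b) for a, b in spans]

    out = []
    for x in reference_positions_kb:
        covering = [
            m for m in aligned if m.offset_kb <= x <= m.offset_kb + m.length_kb
        ]
        if not covering:
            out.append(PositionalOverlap(x, 0, 0, float("nan"), float("nan"), 1.0))
            continue
        n_hit = 0
        for m in covering:
            gs = genome_spans(m, spans_by.get(m.molecule_id, []))
            if any(a <= x <= b for a, b in gs):
                n_hit += 1
        frac = n_hit / len(covering)
        null_hits = np.zeros(n_perm)
        for b in range(n_perm):
            tot = 0
            for m in covering:
                for a0, b0 in spans_by.get(m.molecule_id, []):
                    w = b0 - a0
                    if w >= m.length_kb:
                        tot += 1
                        break
                    start = rng.uniform(0, m.length_kb - w)
                    if start + m.offset_kb <= x <= start + m.offset_kb + w:
                        tot += 1
                        break
            null_hits[b] = tot
        p = float((1 + np.sum(null_hits >= n_hit)) / (n_perm + 1))
        out.append(
            PositionalOverlap(
                x, len(covering), n_hit, frac, float(null_hits.mean()) / len(covering), p
            )
        )
    return out
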