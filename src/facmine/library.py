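"""Closed-form statistics for random-shear large-insert library design.

For a library of N fixed-size inserts of length I placed uniformly on a
genome of length G, a cluster of length L <= I is fully contained by a single
insert iff the insert start falls in one of w = I - L + 1 favorable positions
out of S = G - I + 1 placeable starts. The per-library capture probability is
the binomial complement

    p = 1 - (1 - w/S)**N

with the familiar Poisson limit 1 - exp(-N*w/S) when w/S is small. Coverage
depth is the usual c = N*I/G. These closed forms treat the genome as a single
linear molecule with fixed insert size; multi-chromosome genomes sum placeable
starts per chromosome, and variable-size designs are evaluated by Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import _draw_placements

__all__ = [
    "LibraryDesign",
    "coverage_depth",
    "capture_probability",
    "expected_clusters_captured",
    "clones_for_capture",
    "monte_carlo_capture",
    "design_report",
    "UnattainableError",
]


class UnattainableError(ValueError):
    """The requested capture probability cannot be reached for any N."""


@dataclass(frozen=True)
class LibraryDesign:
    """Library sizing parameters: N clones of I bp on a G bp genome."""

    n_clones: int
    insert_len: int
    genome_len: int

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ValueError("n_clones must be non-negative")
        if not 0 < self.insert_len <= self.genome_len:
            raise ValueError("need 0 < insert_len <= genome_len")


def coverage_depth(design: LibraryDesign) -> float:
    """Fold genome coverage N*I/G (dimensionless)."""
    if design.genome_len == 0:
        raise ValueError("genome length must be positive")
    return design.n_clones * design.insert_len / design.genome_len


def _favorable_fraction(cluster_len: int, insert_len: int, genome_len: int) -> float:
    """w/S: fraction of placeable starts whose insert contains the cluster."""
    w = max(0, insert_len - cluster_len + 1)
    s = genome_len - insert_len + 1
    return min(1.0, w / s)


def capture_probability(cluster_len: int, design: LibraryDesign) -> float:
    """Probability that at least one insert fully contains the cluster.

    Exact binomial form p = 1 - (1 - w/S)**N with w = max(0, I - L + 1)
    favorable starts out of S = G - I + 1; zero when the cluster is longer
    than the insert. Edge effects (clusters within I bp of a chromosome end)
    are not modeled; this is the interior-cluster value.
    """
    if cluster_len <= 0:
        raise ValueError("cluster_len must be positive")
    if cluster_len > design.insert_len or design.n_clones == 0:
        return 0.0
    q = _favorable_fraction(cluster_len, design.insert_len, design.genome_len)
    # log1p keeps precision when q is tiny and N huge
    return -math.expm1(design.n_clones * math.log1p(-q)) if q < 1.0 else 1.0


def expected_clusters_captured(clusters: Sequence, design: LibraryDesign) -> float:
    """Expected number of clusters captured intact: sum of per-cluster
    capture probabilities (clusters treated independently)."""
    return float(sum(capture_probability(c.end - c.start, design) for c in clusters))


def clones_for_capture(
    p_target: float,
    cluster_len: int,
    insert_len: int,
    genome_len: int,
) -> int:
    """Smallest clone count N with capture probability >= ``p_target``.

    Computed as ceil(ln(1 - p_target) / ln(1 - w/S)).

    Raises
    ------
    UnattainableError
        If the cluster is longer than the insert (w = 0), so no library size
        can capture it.
    """
    if not 0.0 <= p_target < 1.0:
        raise ValueError("p_target must be in [0, 1)")
    if cluster_len > insert_len:
        raise UnattainableError(
            f"cluster of {cluster_len} bp cannot fit in a {insert_len} bp insert"
        )
    if p_target == 0.0:
        return 0
    q = _favorable_fraction(cluster_len, insert_len, genome_len)
    if q >= 1.0:
        return 1
    n = math.ceil(math.log1p(-p_target) / math.log1p(-q))
    # guard against float rounding at the boundary
    while capture_probability(cluster_len, LibraryDesign(n, insert_len, genome_len)) < p_target:
        n += 1
    while n > 0 and capture_probability(
        cluster_len, LibraryDesign(n - 1, insert_len, genome_len)
    ) >= p_target:
        n -= 1
    return n


def monte_carlo_capture(
    cluster_len: int,
    design: LibraryDesign,
    n_libraries: int = 10_000,
    seed: int = 0,
    cluster_start: int | None = None,
    chunk: int = 500,
) -> float:
    """Monte-Carlo estimate of the intact-capture probability.

    Simulates ``n_libraries`` independent libraries using the same placement
    rule as :func:`facmine.simulate.simulate_library` (uniform starts over the
    placeable positions of a single linear chromosome) and reports the
    fraction of libraries in which at least one insert contains the cluster.
    The cluster is centered in the genome unless ``cluster_start`` is given.
    Placements are drawn in chunks to bound memory.
    """
    if cluster_len <= 0 or cluster_len > design.genome_len:
        raise ValueError("invalid cluster length")
    start = (
        (design.genome_len - cluster_len) // 2 if cluster_start is None else cluster_start
    )
    end = start + cluster_len
    lo = max(0, end - design.insert_len)  # smallest containing start
    hi = start  # largest containing start
    rng = np.random.default_rng(seed)
    lengths = np.array([design.genome_len], dtype=np.int64)
    captured = 0
    done = 0
    while done < n_libraries:
        m = min(chunk, n_libraries - done)
        _, starts = _draw_placements(rng, lengths, m * design.n_clones, design.insert_len)
        starts = starts.reshape(m, design.n_clones)
        hit = ((starts >= lo) & (starts <= hi)).any(axis=1)
        captured += int(hit.sum())
        done += m
    return captured / n_libraries


def design_report(clusters: Sequence, design: LibraryDesign) -> dict:
    """JSON-ready design summary: coverage, per-cluster capture probability,
    expected number of clusters captured intact."""
    per_cluster = {
        c.cluster_id: capture_probability(c.end - c.start, design) for c in clusters
    }
    return {
        "n_clones": design.n_clones,
        "insert_len": design.insert_len,
        "genome_len": design.genome_len,
        "coverage_depth": coverage_depth(design),
        "capture_probability": per_cluster,
        "expected_clusters_captured": float(sum(per_cluster.values())),
        "n_clusters": len(per_cluster),
    }
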