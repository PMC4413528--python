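"""Synthetic data with known ground truth for the whole pipeline.

Four generators mirror the four experimental inputs:

* :func:`simulate_genome` — a reference genome carrying non-overlapping
  secondary-metabolite (SM) gene-cluster annotations, 30–80 kb by default.
* :func:`simulate_library` — a random-shear large-insert clone library,
  inserts placed uniformly over each chromosome's placeable positions.
* :func:`simulate_end_alignments` — paired end-read alignments at the exact
  insert edges, with optional single-end dropout (producing downstream
  "one end only" calls).
* :func:`simulate_metabolome` — multi-strain LC-HRMS feature lists with shared
  background compounds, planted strain-unique compounds, ppm-scale mass error,
  retention-time jitter, log-normal intensities and optional dropout, in a
  biological x technical replicate layout.

All coordinates are 0-based, half-open. Every generator is deterministic for
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compounds import FUNGAL_METABOLITES
from .derep import adduct_mz, formula_mass
from .mapping import EndAlignment

__all__ = [
    "CapacityError",
    "GenomeSpec",
    "ClusterAnnotation",
    "SimClone",
    "MetabolomeDesign",
    "PlantedCompound",
    "GroundTruth",
    "simulate_genome",
    "simulate_library",
    "simulate_end_alignments",
    "simulate_metabolome",
    "default_screen_design",
]


class CapacityError(ValueError):
    """Requested annotations or inserts cannot be packed into the genome."""


@dataclass(frozen=True)
class GenomeSpec:
    """A simulated reference genome: chromosome lengths (bp) and a seed."""

    chrom_lengths: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class ClusterAnnotation:
    """A named genomic interval for one SM gene cluster (0-based, half-open)."""

    cluster_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.cluster_id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimClone:
    """True insert interval of one simulated clone (0-based, half-open)."""

    clone_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def simulate_genome(
    spec: GenomeSpec,
    n_clusters: int,
    size_range: tuple[int, int] = (30_000, 80_000),
    min_gap: int = 10_000,
    seed: int | None = None,
) -> list[ClusterAnnotation]:
    """Place ``n_clusters`` non-overlapping cluster intervals on the genome.

    Cluster sizes are uniform integers in ``size_range`` (inclusive). Clusters
    on the same chromosome are separated by at least ``min_gap`` bp. Clusters
    are spread across chromosomes with probability proportional to chromosome
    length and positioned by drawing uniform slack offsets, so placement is
    close to uniform over valid configurations.

    Raises
    ------
    CapacityError
        If ``n_clusters * (max size + min_gap)`` exceeds the genome length, or
        a chromosome allocation cannot accommodate its clusters.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be non-negative")
    smin, smax = size_range
    if not (0 < smin <= smax):
        raise ValueError("size_range must satisfy 0 < min <= max")
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    if n_clusters == 0:
        return []
    if n_clusters * (smax + min_gap) > spec.total_length:
        raise CapacityError(
            f"cannot pack {n_clusters} clusters of up to {smax} bp with {min_gap} bp "
            f"gaps into a {spec.total_length} bp genome"
        )

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in names], dtype=np.int64)
    # per-chromosome capacity: k clusters need k*smax + (k-1)*min_gap bp
    caps = (lengths + min_gap) // (smax + min_gap)
    if caps.sum() < n_clusters:
        raise CapacityError("per-chromosome capacities cannot hold the requested clusters")

    probs = lengths / lengths.sum()
    alloc = rng.multinomial(n_clusters, probs)
    # rebalance any chromosome drawn over capacity onto ones with slack
    for i in np.argsort(-(alloc - caps)):
        while alloc[i] > caps[i]:
            slack = np.flatnonzero(alloc < caps)
            j = slack[0]
            alloc[i] -= 1
            alloc[j] += 1

    annotations: list[ClusterAnnotation] = []
    for name, length, k in zip(names, lengths, alloc):
        if k == 0:
            continue
        sizes = rng.integers(smin, smax + 1, size=int(k))
        free = int(length) - int(sizes.sum()) - (int(k) - 1) * min_gap
        if free < 0:
            raise CapacityError(f"chromosome {name!r} cannot hold {k} clusters")
        offsets = np.sort(rng.integers(0, free + 1, size=int(k)))
        pos = offsets + np.concatenate(([0], np.cumsum(sizes[:-1]))) + np.arange(int(k)) * min_gap
        for start, size in zip(pos, sizes):
            annotations.append(
                ClusterAnnotation("", name, int(start), int(start) + int(size))
            )

    order = sorted(range(len(annotations)), key=lambda i: (names.index(annotations[i].chrom), annotations[i].start))
    width = max(2, len(str(n_clusters)))
    return [
        ClusterAnnotation(f"cluster_{rank + 1:0{width}d}", a.chrom, a.start, a.end)
        for rank, i in enumerate(order)
        for a in [annotations[i]]
    ]


def _draw_placements(
    rng: np.random.Generator,
    chrom_lengths: np.ndarray,
    n: int,
    insert: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (chromosome index, start) for ``n`` fixed-size inserts.

    Chromosomes are chosen proportional to their placeable start count
    (L - insert + 1); starts are uniform on [0, L - insert]. This is the
    placement rule of :func:`simulate_library`, factored out so Monte-Carlo
    capture estimates can reuse it vectorized.
    """
    placeable = chrom_lengths - insert + 1
    if (placeable <= 0).all():
        raise CapacityError(f"insert size {insert} exceeds every chromosome length")
    weights = np.where(placeable > 0, placeable, 0).astype(float)
    if len(chrom_lengths) == 1:
        chrom_idx = np.zeros(n, dtype=np.int64)
    else:
        chrom_idx = rng.choice(len(chrom_lengths), size=n, p=weights / weights.sum())
    starts = np.floor(rng.random(n) * placeable[chrom_idx]).astype(np.int64)
    return chrom_idx, starts


def simulate_library(
    spec: GenomeSpec,
    n_clones: int,
    insert_size: int | Callable[[np.random.Generator, int], np.ndarray],
    seed: int | None = None,
) -> list[SimClone]:
    """Simulate a random-shear clone library of ``n_clones`` inserts.

    ``insert_size`` is either a fixed length in bp or a callable
    ``f(rng, n) -> array of n lengths`` for variable-size designs. Each insert
    lands on a chromosome with probability proportional to its placeable start
    count, with the start uniform over [0, L - insert].
    """
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in names], dtype=np.int64)
    if n_clones == 0:
        return []
    width = max(5, len(str(n_clones)))

    if callable(insert_size):
        sizes = np.asarray(insert_size(rng, n_clones), dtype=np.int64)
        if (sizes <= 0).any():
            raise ValueError("drawn insert sizes must be positive")
        clones = []
        for i, size in enumerate(sizes):
            placeable = lengths - int(size) + 1
            if (placeable <= 0).all():
                raise CapacityError(f"insert size {size} exceeds every chromosome length")
            weights = np.where(placeable > 0, placeable, 0).astype(float)
            ci = int(rng.choice(len(names), p=weights / weights.sum()))
            start = int(np.floor(rng.random() * placeable[ci]))
            clones.append(
                SimClone(f"clone_{i + 1:0{width}d}", names[ci], start, start + int(size))
            )
        return clones

    insert = int(insert_size)
    if insert <= 0:
        raise ValueError("insert_size must be positive")
    chrom_idx, starts = _draw_placements(rng, lengths, n_clones, insert)
    return [
        SimClone(f"clone_{i + 1:0{width}d}", names[int(ci)], int(s), int(s) + insert)
        for i, (ci, s) in enumerate(zip(chrom_idx, starts))
    ]


def simulate_end_alignments(
    clones: Sequence[SimClone],
    read_len: int = 800,
    one_end_dropout: float = 0.0,
    seed: int = 0,
) -> list[EndAlignment]:
    """Emit end-read alignment records at the exact edges of each insert.

    The forward end read covers [start, start + read_len) on the + strand, the
    reverse end read [end - read_len, end) on the - strand. With probability
    ``one_end_dropout`` one of the two records (chosen at random) is omitted,
    so the clone can only be mapped from a single end. Alignment identity is
    reported as 100.0; no sequencing-error model is applied.
    """
    if not (0.0 <= one_end_dropout <= 1.0):
        raise ValueError("one_end_dropout must be a probability")
    for clone in clones:
        if read_len >= clone.length:
            raise ValueError(f"read_len {read_len} >= insert length of {clone.clone_id}")
    rng = np.random.default_rng(seed)
    drop = rng.random(len(clones)) < one_end_dropout
    which = rng.integers(0, 2, size=len(clones))  # 0 -> drop F, 1 -> drop R
    records: list[EndAlignment] = []
    for clone, d, w in zip(clones, drop, which):
        if not (d and w == 0):
            records.append(
                EndAlignment(clone.clone_id, "F", clone.chrom, clone.start, clone.start + read_len, "+", 100.0)
            )
        if not (d and w == 1):
            records.append(
                EndAlignment(clone.clone_id, "R", clone.chrom, clone.end - read_len, clone.end, "-", 100.0)
            )
    return records


@dataclass(frozen=True)
class MetabolomeDesign:
    """Layout and noise model for a simulated multi-strain LC-HRMS experiment.

    One strain (``control_strain``, defaulting to the first) carries the empty
    vector; every strain contributes ``biological_replicates`` cultures each
    measured in ``technical_replicates`` injections. Background compounds are
    present in every strain at consistent levels; planted unique compounds
    appear only in their designated strain. Observed m/z is perturbed by a
    zero-mean Gaussian relative error (``mass_error_ppm_sd``, in ppm) and RT
    by Gaussian jitter in minutes. Intensities follow a per-compound base
    level, log-normal with the given location/scale (natural-log units), times
    a per-measurement log-normal factor (``intensity_noise_sd``). ``dropout_rate``
    is the probability that a truly present compound is missed for one
    biological replicate (both technical injections miss it together).
    """

    strains: tuple[str, ...]
    control_strain: str | None = None
    biological_replicates: int = 3
    technical_replicates: int = 2
    n_background_compounds: int = 12
    n_unique_per_strain: Mapping[str, int] = field(default_factory=dict)
    mz_range: tuple[float, float] = (200.0, 1500.0)
    rt_range: tuple[float, float] = (2.0, 45.0)
    mass_error_ppm_sd: float = 1.0
    rt_jitter_sd: float = 0.2
    intensity_location: float = math.log(8e7)
    intensity_scale: float = 0.5
    intensity_noise_sd: float = 0.2
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if not self.strains:
            raise ValueError("need at least one strain")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain names must be unique")
        control = self.control_strain if self.control_strain is not None else self.strains[0]
        if control not in self.strains:
            raise ValueError(f"control strain {control!r} not in strains")
        object.__setattr__(self, "control_strain", control)
        if self.biological_replicates < 1 or self.technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must have low < high")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be a probability")
        if self.n_background_compounds < 0:
            raise ValueError("n_background_compounds must be non-negative")
        for strain, k in self.n_unique_per_strain.items():
            if strain not in self.strains:
                raise ValueError(f"unique-compound strain {strain!r} not in strains")
            if k < 0:
                raise ValueError("unique counts must be non-negative")

    def sample_ids(self) -> dict[str, str]:
        """Deterministic sample_id -> strain map for the full replicate layout."""
        out: dict[str, str] = {}
        for strain in self.strains:
            for b in range(1, self.biological_replicates + 1):
                for t in range(1, self.technical_replicates + 1):
                    out[f"{strain}_b{b}_t{t}"] = strain
        return out


@dataclass(frozen=True)
class PlantedCompound:
    """Ground-truth compound: true (noise-free) m/z and RT, formula if real."""

    name: str
    formula: str | None
    mz: float
    rt: float


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows: background list, per-strain uniques, design."""

    background: tuple[PlantedCompound, ...]
    unique: Mapping[str, tuple[PlantedCompound, ...]]
    samples: Mapping[str, str]


def simulate_metabolome(design: MetabolomeDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate per-sample LC-HRMS feature lists plus ground truth.

    Planted compounds take real molecular formulas from the built-in fungal
    metabolite table (observed as [M+H]+ ions), drawn without replacement in a
    seeded random order, so unique compounds never recur in another strain.
    Background compounds beyond the table get synthetic masses uniform in
    ``mz_range``. Returns a feature table with columns
    ``sample_id, mz, rt_min, intensity`` and the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(design.seed)
    low, high = design.mz_range

    eligible = []
    for name, formula in FUNGAL_METABOLITES:
        mz = adduct_mz(formula_mass(formula), "[M+H]+")
        if low <= mz <= high:
            eligible.append((name, formula, mz))
    pool = [eligible[i] for i in rng.permutation(len(eligible))]

    def _take_real() -> tuple[str, str, float] | None:
        return pool.pop() if pool else None

    unique: dict[str, list[PlantedCompound]] = {}
    for strain in design.strains:
        k = design.n_unique_per_strain.get(strain, 0)
        picks = []
        for _ in range(k):
            item = _take_real()
            if item is None:
                raise ValueError("built-in compound table exhausted for unique compounds")
            picks.append(item)
        unique[strain] = [PlantedCompound(n, f, mz, 0.0) for n, f, mz in picks]

    background: list[PlantedCompound] = []
    for i in range(design.n_background_compounds):
        item = _take_real()
        if item is not None:
            name, formula, mz = item
            background.append(PlantedCompound(name, formula, mz, 0.0))
        else:
            background.append(
                PlantedCompound(f"background_{i + 1:02d}", None, float(rng.uniform(low, high)), 0.0)
            )

    # assign retention times and base intensities in one deterministic pass
    ordered: list[tuple[str | None, PlantedCompound]] = [(None, c) for c in background]
    for strain in design.strains:
        ordered.extend((strain, c) for c in unique[strain])
    rts = rng.uniform(*design.rt_range, size=len(ordered))
    bases = np.exp(rng.normal(design.intensity_location, design.intensity_scale, size=len(ordered)))

    background = []
    unique = {s: [] for s in design.strains}
    base_of: dict[tuple[str | None, str], float] = {}
    for (strain, comp), rt, base in zip(ordered, rts, bases):
        placed = PlantedCompound(comp.name, comp.formula, comp.mz, float(rt))
        if strain is None:
            background.append(placed)
        else:
            unique[strain].append(placed)
        base_of[(strain, comp.name)] = float(base)

    rows: list[tuple[str, float, float, float]] = []
    for strain in design.strains:
        strain_compounds = [(None, c) for c in background] + [(strain, c) for c in unique[strain]]
        for b in range(1, design.biological_replicates + 1):
            dropped = rng.random(len(strain_compounds)) < design.dropout_rate
            for t in range(1, design.technical_replicates + 1):
                sid = f"{strain}_b{b}_t{t}"
                for (owner, comp), miss in zip(strain_compounds, dropped):
                    if miss:
                        continue
                    mz_obs = comp.mz * (1.0 + rng.normal(0.0, design.mass_error_ppm_sd * 1e-6))
                    rt_obs = max(0.0, comp.rt + rng.normal(0.0, design.rt_jitter_sd))
                    inten = base_of[(owner, comp.name)] * math.exp(
                        rng.normal(0.0, design.intensity_noise_sd)
                    )
                    rows.append((sid, mz_obs, rt_obs, inten))

    features = pd.DataFrame(rows, columns=["sample_id", "mz", "rt_min", "intensity"])
    truth = GroundTruth(
        background=tuple(background),
        unique={s: tuple(v) for s, v in unique.items()},
        samples=design.sample_ids(),
    )
    return features, truth


def default_screen_design(
    seed: int = 0,
    target: str = "FAC01",
    n_unique_target: int = 1,
    dropout_rate: float = 0.0,
) -> MetabolomeDesign:
    """The reference screening layout: an empty-vector control plus 14 FAC
    strains, 3 biological x 2 technical replicates, 12 shared background
    compounds, and ``n_unique_target`` compounds planted in the target strain.
    """
    strains = ("EV_control",) + tuple(f"FAC{i:02d}" for i in range(1, 15))
    if target not in strains:
        raise ValueError(f"target {target!r} not in the default strain panel")
    return MetabolomeDesign(
        strains=strains,
        control_strain="EV_control",
        n_unique_per_strain={target: n_unique_target} if n_unique_target else {},
        dropout_rate=dropout_rate,
        seed=seed,
    )
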