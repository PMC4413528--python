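"""Clone insert inference from paired end-read alignments, and selection of
candidate cluster-containing clones.

A large-insert clone whose two end reads map to the same chromosome, on
opposite strands facing inward, and at a plausible separation brackets its
insert interval on the reference. Clones whose inferred interval fully
contains an SM cluster annotation — including flanking sequence on both sides
— are candidate clones for intact-cluster capture; clones overlapping a
cluster without containing it give only partial capture.

Status vocabulary: insert calls are BOTH_ENDS / ONE_END_ONLY / DISCORDANT /
UNMAPPED; cluster capture calls are INTACT / PARTIAL_ONLY / MISSING.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ClusterAnnotation

__all__ = [
    "EndAlignment",
    "InsertStatus",
    "InsertCall",
    "Containment",
    "CaptureStatus",
    "CandidateClone",
    "ClusterCaptureCall",
    "InsertConfig",
    "infer_insert",
    "infer_inserts",
    "classify_containment",
    "select_candidate_facs",
    "capture_report",
]


@dataclass(frozen=True)
class EndAlignment:
    """One end-read alignment (0-based, half-open reference coordinates)."""

    clone_id: str
    end_label: str  # "F" or "R"
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    identity: float = 100.0
    aln_length: int | None = None

    def __post_init__(self) -> None:
        if self.end_label not in ("F", "R"):
            raise ValueError(f"end_label must be F or R, got {self.end_label!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.ref_start < self.ref_end:
            raise ValueError(f"{self.clone_id}/{self.end_label}: empty alignment interval")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        if self.aln_length is None:
            object.__setattr__(self, "aln_length", self.ref_end - self.ref_start)


class InsertStatus(str, Enum):
    BOTH_ENDS = "BOTH_ENDS"
    ONE_END_ONLY = "ONE_END_ONLY"
    DISCORDANT = "DISCORDANT"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class InsertCall:
    """Inferred insert interval for one clone; interval only for BOTH_ENDS."""

    clone_id: str
    status: InsertStatus
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        has_interval = self.chrom is not None and self.start is not None and self.end is not None
        if (self.status is InsertStatus.BOTH_ENDS) != has_interval:
            raise ValueError("interval present iff status is BOTH_ENDS")


@dataclass(frozen=True)
class InsertConfig:
    """Plausible insert-span window in bp; spans outside it are discordant.

    The default window of 20–300 kb brackets random-shear large-insert
    libraries, whose inserts can reach ~300 kb.
    """

    min_insert: int = 20_000
    max_insert: int = 300_000

    def __post_init__(self) -> None:
        if not 0 < self.min_insert <= self.max_insert:
            raise ValueError("need 0 < min_insert <= max_insert")


def _best_per_end(records: Sequence[EndAlignment]) -> dict[str, EndAlignment]:
    """Keep one alignment per end: highest identity, then longest alignment,
    then leftmost position (repeat hits are common for large genomes)."""
    best: dict[str, EndAlignment] = {}
    for rec in records:
        cur = best.get(rec.end_label)
        if cur is None:
            best[rec.end_label] = rec
            continue
        key = (rec.identity, rec.aln_length, -rec.ref_start)
        cur_key = (cur.identity, cur.aln_length, -cur.ref_start)
        if key > cur_key:
            best[rec.end_label] = rec
    return best


def infer_insert(records: Sequence[EndAlignment], config: InsertConfig = InsertConfig()) -> InsertCall:
    """Infer one clone's insert interval from its end alignments.

    BOTH_ENDS requires the two surviving end records to share a chromosome,
    lie on opposite strands facing inward (the + strand read leftmost), and
    imply a span inside ``[min_insert, max_insert]``; the interval is then
    [leftmost ref_start, rightmost ref_end). A single mapped end gives
    ONE_END_ONLY; no records give UNMAPPED; anything else is DISCORDANT.

    Raises
    ------
    ValueError
        If the records carry more than one clone_id.
    """
    clone_ids = {r.clone_id for r in records}
    if len(clone_ids) > 1:
        raise ValueError(f"records mix clone ids: {sorted(clone_ids)}")
    if not records:
        return InsertCall("", InsertStatus.UNMAPPED)
    clone_id = records[0].clone_id
    best = _best_per_end(records)
    if len(best) == 1:
        return InsertCall(clone_id, InsertStatus.ONE_END_ONLY)
    a, b = best["F"], best["R"]
    if a.chrom != b.chrom or a.strand == b.strand:
        return InsertCall(clone_id, InsertStatus.DISCORDANT)
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    if plus.ref_start > minus.ref_start:  # outward-facing
        return InsertCall(clone_id, InsertStatus.DISCORDANT)
    start = min(a.ref_start, b.ref_start)
    end = max(a.ref_end, b.ref_end)
    if not (config.min_insert <= end - start <= config.max_insert):
        return InsertCall(clone_id, InsertStatus.DISCORDANT)
    return InsertCall(clone_id, InsertStatus.BOTH_ENDS, a.chrom, start, end)


def infer_inserts(
    records: Iterable[EndAlignment],
    config: InsertConfig = InsertConfig(),
    all_clone_ids: Iterable[str] | None = None,
) -> list[InsertCall]:
    """Group alignments by clone and infer every insert call.

    ``all_clone_ids`` may list clones with no alignments at all, which are
    reported UNMAPPED. Output is sorted by clone_id.
    """
    grouped: dict[str, list[EndAlignment]] = defaultdict(list)
    for rec in records:
        grouped[rec.clone_id].append(rec)
    calls = [infer_insert(recs, config) for recs in grouped.values()]
    if all_clone_ids is not None:
        for cid in all_clone_ids:
            if cid not in grouped:
                calls.append(InsertCall(cid, InsertStatus.UNMAPPED))
    return sorted(calls, key=lambda c: c.clone_id)


class Containment(str, Enum):
    INTACT = "INTACT"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


def classify_containment(insert: tuple[int, int], cluster: tuple[int, int]) -> Containment:
    """Classify a same-chromosome insert/cluster interval pair.

    INTACT if the insert fully contains the cluster, PARTIAL if they overlap
    without containment, NONE if disjoint. Intervals are half-open (start, end).
    """
    istart, iend = insert
    cstart, cend = cluster
    if istart <= cstart and cend <= iend:
        return Containment.INTACT
    if min(iend, cend) > max(istart, cstart):
        return Containment.PARTIAL
    return Containment.NONE


class CaptureStatus(str, Enum):
    INTACT = "INTACT"
    PARTIAL_ONLY = "PARTIAL_ONLY"
    MISSING = "MISSING"


@dataclass(frozen=True)
class CandidateClone:
    """A clone overlapping a cluster, with its flank sizes (bp).

    For containing clones both flanks are >= 0; the ranking key is the
    smaller flank, so the top candidate carries the most context on its
    weaker side. For partial overlaps a flank can be negative (the clone ends
    inside the cluster by that amount).
    """

    clone_id: str
    left_flank: int
    right_flank: int

    @property
    def min_flank(self) -> int:
        return min(self.left_flank, self.right_flank)


@dataclass(frozen=True)
class ClusterCaptureCall:
    """Capture verdict for one cluster with its ranked candidate clones."""

    cluster_id: str
    status: CaptureStatus
    candidates: tuple[CandidateClone, ...] = field(default=())


def select_candidate_facs(
    inserts: Sequence[InsertCall],
    clusters: Sequence["ClusterAnnotation"],
) -> list[ClusterCaptureCall]:
    """Select candidate cluster-containing clones for every cluster.

    Only BOTH_ENDS inserts participate. A cluster with at least one fully
    containing clone is INTACT, its candidates ranked by min(left flank,
    right flank) descending (ties by clone_id ascending). A cluster touched
    only partially is PARTIAL_ONLY with the overlapping clones listed by
    overlap descending. Untouched clusters are MISSING.

    Raises
    ------
    ValueError
        If two insert calls share a clone_id.
    """
    seen: set[str] = set()
    mapped: list[InsertCall] = []
    for call in inserts:
        if call.clone_id in seen:
            raise ValueError(f"duplicate insert call for clone {call.clone_id!r}")
        seen.add(call.clone_id)
        if call.status is InsertStatus.BOTH_ENDS:
            mapped.append(call)

    out: list[ClusterCaptureCall] = []
    for cluster in clusters:
        intact: list[CandidateClone] = []
        partial: list[tuple[int, CandidateClone]] = []
        for ins in mapped:
            if ins.chrom != cluster.chrom:
                continue
            rel = classify_containment((ins.start, ins.end), (cluster.start, cluster.end))
            cand = CandidateClone(
                ins.clone_id,
                left_flank=cluster.start - ins.start,
                right_flank=ins.end - cluster.end,
            )
            if rel is Containment.INTACT:
                intact.append(cand)
            elif rel is Containment.PARTIAL:
                overlap = min(ins.end, cluster.end) - max(ins.start, cluster.start)
                partial.append((overlap, cand))
        if intact:
            intact.sort(key=lambda c: (-c.min_flank, c.clone_id))
            out.append(ClusterCaptureCall(cluster.cluster_id, CaptureStatus.INTACT, tuple(intact)))
        elif partial:
            partial.sort(key=lambda p: (-p[0], p[1].clone_id))
            out.append(
                ClusterCaptureCall(
                    cluster.cluster_id, CaptureStatus.PARTIAL_ONLY, tuple(c for _, c in partial)
                )
            )
        else:
            out.append(ClusterCaptureCall(cluster.cluster_id, CaptureStatus.MISSING))
    return out


def capture_report(calls: Sequence[ClusterCaptureCall]) -> dict[str, int]:
    """Summary counts partitioning the cluster set by capture status."""
    counts = {"intact": 0, "partial_only": 0, "missing": 0}
    for call in calls:
        if call.status is CaptureStatus.INTACT:
            counts["intact"] += 1
        elif call.status is CaptureStatus.PARTIAL_ONLY:
            counts["partial_only"] += 1
        else:
            counts["missing"] += 1
    return counts
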