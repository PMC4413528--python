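"""Readers and writers for the pipeline's file formats.

Intervals travel as BED (0-based, half-open) or GFF3 (converted to and from
1-based inclusive); end-read alignments use the 12-column tabular alignment
dialect (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) with the end encoded as a ``/F`` or ``/R`` query suffix and
the strand by the subject coordinate order. Feature lists are CSV
(sample_id, mz, rt_min, intensity); designs are TSV (sample_id, strain) or
embedded in the ground-truth JSON; compound databases are CSV with a name and
a formula and/or monoisotopic mass. Lines starting with ``#`` are treated as
comments everywhere, which is where run provenance headers go.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .derep import CompoundRecord
from .mapping import ClusterCaptureCall, EndAlignment
from .simulate import ClusterAnnotation, GroundTruth, PlantedCompound, SimClone

__all__ = [
    "read_clusters",
    "write_clusters_bed",
    "write_clusters_gff3",
    "write_clones_bed",
    "read_clones_bed",
    "read_alignments",
    "write_alignments",
    "read_features_csv",
    "write_features_csv",
    "read_design",
    "write_design_tsv",
    "read_ground_truth",
    "write_ground_truth",
    "read_compound_db",
    "write_capture_table",
]

ALIGNMENT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def _write_lines(path: str | Path, lines: Iterable[str], header_lines: Sequence[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------- intervals

def write_clusters_bed(
    clusters: Sequence[ClusterAnnotation],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    _write_lines(
        path,
        (f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}" for c in clusters),
        header_lines,
    )


def write_clusters_gff3(
    clusters: Sequence[ClusterAnnotation],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    lines = ["##gff-version 3"]
    for c in clusters:
        lines.append(
            f"{c.chrom}\tfacmine\tSM_cluster\t{c.start + 1}\t{c.end}\t.\t.\t.\t"
            f"ID={c.cluster_id};Name={c.cluster_id}"
        )
    _write_lines(path, lines, header_lines)


def _read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            out.append((chrom, start, end, name))
    return out


def _read_gff3_clusters(path: str | Path) -> list[ClusterAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    clusters = []
    for feat in db.all_features(order_by=("seqid", "start")):
        name = feat.attributes.get("ID", [feat.id])[0]
        clusters.append(ClusterAnnotation(name, feat.seqid, feat.start - 1, feat.end))
    return clusters


def read_clusters(path: str | Path) -> list[ClusterAnnotation]:
    """Read cluster annotations from BED or GFF3 (by file extension)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3_clusters(path)
    return [ClusterAnnotation(name, chrom, s, e) for chrom, s, e, name in _read_bed(path)]


def write_clones_bed(
    clones: Sequence[SimClone],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    _write_lines(
        path,
        (f"{c.chrom}\t{c.start}\t{c.end}\t{c.clone_id}" for c in clones),
        header_lines,
    )


def read_clones_bed(path: str | Path) -> list[SimClone]:
    return [SimClone(name, chrom, s, e) for chrom, s, e, name in _read_bed(path)]


# --------------------------------------------------------------- alignments

def write_alignments(
    records: Sequence[EndAlignment],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    """Write end alignments in the 12-column tabular dialect.

    Subject coordinates are 1-based inclusive; minus-strand hits have
    sstart > send, as aligners emit them.
    """
    lines = []
    for r in records:
        if r.strand == "+":
            sstart, send = r.ref_start + 1, r.ref_end
        else:
            sstart, send = r.ref_end, r.ref_start + 1
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    f"{r.clone_id}/{r.end_label}",
                    r.chrom,
                    f"{r.identity:.1f}",
                    r.aln_length,
                    0,
                    0,
                    1,
                    r.aln_length,
                    sstart,
                    send,
                    "0.0",
                    f"{1.8 * r.aln_length:.1f}",
                )
            )
        )
    _write_lines(path, lines, header_lines)


def read_alignments(path: str | Path) -> list[EndAlignment]:
    """Parse a 12-column tabular alignment file into end alignments.

    The query id must carry a ``/F`` or ``/R`` suffix naming the clone end.
    Malformed lines raise with the offending line number.
    """
    records: list[EndAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            qseqid, sseqid = parts[0], parts[1]
            if "/" not in qseqid or qseqid.rsplit("/", 1)[1] not in ("F", "R"):
                raise ValueError(
                    f"{path}: line {lineno}: query id {qseqid!r} lacks an /F or /R end suffix"
                )
            clone_id, end_label = qseqid.rsplit("/", 1)
            try:
                pident = float(parts[2])
                length = int(parts[3])
                sstart, send = int(parts[8]), int(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            records.append(
                EndAlignment(
                    clone_id=clone_id,
                    end_label=end_label,
                    chrom=sseqid,
                    ref_start=lo - 1,
                    ref_end=hi,
                    strand=strand,
                    identity=pident,
                    aln_length=length,
                )
            )
    return records


# ----------------------------------------------------------------- features

def write_features_csv(
    features: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        features.to_csv(fh, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "mz", "rt_min", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return df


def write_design_tsv(
    design: Mapping[str, str],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    lines = ["sample_id\tstrain"]
    lines.extend(f"{sample}\t{strain}" for sample, strain in design.items())
    _write_lines(path, lines, header_lines)


def read_design(path: str | Path) -> dict[str, str]:
    """Read a sample -> strain map from a design TSV or a ground-truth JSON."""
    if Path(path).suffix.lower() == ".json":
        return dict(read_ground_truth(path).samples)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample_id", "strain"} <= set(df.columns):
        raise ValueError(f"{path}: design table needs sample_id and strain columns")
    return dict(zip(df["sample_id"].astype(str), df["strain"].astype(str)))


# ------------------------------------------------------------- ground truth

def _compound_to_json(c: PlantedCompound) -> dict:
    return {"name": c.name, "formula": c.formula, "mz": c.mz, "rt": c.rt}


def write_ground_truth(
    truth: GroundTruth,
    path: str | Path,
    extra: Mapping | None = None,
) -> None:
    payload = {
        "background": [_compound_to_json(c) for c in truth.background],
        "unique": {s: [_compound_to_json(c) for c in v] for s, v in truth.unique.items()},
        "samples": dict(truth.samples),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)

    def _compound(d: dict) -> PlantedCompound:
        return PlantedCompound(d["name"], d.get("formula"), d["mz"], d["rt"])

    return GroundTruth(
        background=tuple(_compound(d) for d in payload["background"]),
        unique={s: tuple(_compound(d) for d in v) for s, v in payload["unique"].items()},
        samples=dict(payload["samples"]),
    )


# ----------------------------------------------------------------- compounds

def read_compound_db(path: str | Path, source: str | None = None) -> list[CompoundRecord]:
    """Read a compound database CSV (columns: name, formula and/or mass, source)."""
    df = pd.read_csv(path, comment="#")
    if "name" not in df.columns:
        raise ValueError(f"{path}: compound table needs a name column")
    records = []
    for _, row in df.iterrows():
        formula = row.get("formula")
        formula = None if pd.isna(formula) or formula == "" else str(formula)
        mass = row.get("mass", row.get("monoisotopic_mass"))
        mass = None if mass is None or pd.isna(mass) else float(mass)
        records.append(
            CompoundRecord(
                name=str(row["name"]),
                formula=formula,
                monoisotopic_mass=mass,
                source=source or str(row.get("source", "") or ""),
            )
        )
    return records


# ------------------------------------------------------------ capture table

def write_capture_table(
    calls: Sequence[ClusterCaptureCall],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    """Write a per-cluster capture TSV: cluster, status, ranked candidates."""
    lines = ["cluster_id\tstatus\tn_candidates\tbest_clone\tbest_min_flank\tcandidates"]
    for call in calls:
        best = call.candidates[0] if call.candidates else None
        cand_str = ",".join(
            f"{c.clone_id}({c.left_flank}|{c.right_flank})" for c in call.candidates
        )
        lines.append(
            "\t".join(
                [
                    call.cluster_id,
                    call.status.value,
                    str(len(call.candidates)),
                    best.clone_id if best else ".",
                    str(best.min_flank) if best else ".",
                    cand_str or ".",
                ]
            )
        )
    _write_lines(path, lines, header_lines)
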