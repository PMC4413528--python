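"""Independent reference implementations used only as test oracles.

These deliberately avoid the library's code paths: the componentizer is a
naive O(n^2) list scan, and the candidate-clone selector enumerates interval
relations directly from the definitions. They exist so the optimized
implementations can be checked for exact agreement on random instances.
"""

from __future__ import annotations


def brute_force_components(rows, mz_tol_ppm=10.0, rt_window_min=2.5, min_intensity=5e6):
    """Naive greedy componentization.

    rows: list of (sample_id, mz, rt, intensity) tuples.
    Returns a list of components, each a sorted list of row indices, in the
    order the seeds were consumed (global intensity descending, ties by
    lower m/z, earlier RT, sample_id).
    """
    remaining = set(range(len(rows)))
    components = []
    while True:
        seeds = [i for i in remaining if rows[i][3] >= min_intensity]
        if not seeds:
            break
        seed = min(seeds, key=lambda i: (-rows[i][3], rows[i][1], rows[i][2], rows[i][0]))
        smz, srt = rows[seed][1], rows[seed][2]
        members = sorted(
            i
            for i in remaining
            if abs(rows[i][1] - smz) <= smz * mz_tol_ppm * 1e-6
            and abs(rows[i][2] - srt) <= rt_window_min
        )
        components.append(members)
        remaining -= set(members)
    return components


def component_signature(rows, member_indices):
    """Canonical summary of one oracle component for comparison:
    (n_features, per-sample summed intensity, weighted mean m/z and RT)."""
    total = sum(rows[i][3] for i in member_indices)
    per_sample: dict[str, float] = {}
    for i in member_indices:
        sid = rows[i][0]
        per_sample[sid] = per_sample.get(sid, 0.0) + rows[i][3]
    if total > 0:
        mz = sum(rows[i][1] * rows[i][3] for i in member_indices) / total
        rt = sum(rows[i][2] * rows[i][3] for i in member_indices) / total
    else:
        mz = rows[member_indices[0]][1]
        rt = rows[member_indices[0]][2]
    return len(member_indices), per_sample, mz, rt


def brute_force_capture(inserts, clusters):
    """Direct-from-definitions candidate selection.

    inserts: list of (clone_id, chrom, start, end) for mapped (both-ends)
    clones only. clusters: list of (cluster_id, chrom, start, end).
    Returns {cluster_id: (status, [clone_id, ...])} with INTACT candidates
    ranked by min flank descending then clone_id, and PARTIAL_ONLY clones by
    overlap descending then clone_id.
    """
    out = {}
    for cid, cchrom, cstart, cend in clusters:
        containing = []
        touching = []
        for qid, qchrom, qstart, qend in inserts:
            if qchrom != cchrom:
                continue
            if qstart <= cstart and cend <= qend:
                flank = min(cstart - qstart, qend - cend)
                containing.append((qid, flank))
            else:
                overlap = min(qend, cend) - max(qstart, cstart)
                if overlap > 0:
                    touching.append((qid, overlap))
        if containing:
            containing.sort(key=lambda t: (-t[1], t[0]))
            out[cid] = ("INTACT", [q for q, _ in containing])
        elif touching:
            touching.sort(key=lambda t: (-t[1], t[0]))
            out[cid] = ("PARTIAL_ONLY", [q for q, _ in touching])
        else:
            out[cid] = ("MISSING", [])
    return out
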