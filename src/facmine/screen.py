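"""Differential LC-HRMS screening: component detection, TIC normalization,
replicate presence calls, target-vs-control uniqueness filtering, and a
decoy-based false-discovery estimate.

The screen is presence/absence, not fold change: a component is a cross-sample
entity grouped from centroided features agreeing in m/z (ppm tolerance,
default 10 ppm) and retention time (default 2.5 min); it is "present" in a
strain only if its raw intensity clears the seeding threshold (default 5e6)
in every replicate of that strain, and "unique" to the target strain if it is
present there and in no control strain. The decoy estimate reruns the same
filter with each control strain posing as the target, giving an empirical
null for the unique-component count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .derep import DEFAULT_ADDUCTS, CompoundRecord, adduct_mz, ppm_error

__all__ = [
    "ScreenConfig",
    "Component",
    "ScreenResult",
    "detect_components",
    "sample_tics",
    "normalize_tic",
    "presence_calls",
    "uniqueness_filter",
    "decoy_fdr",
    "monitor_known_compounds",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Analysis tolerances.

    mz_tol_ppm : maximum |Δm/z| from the component seed, in ppm (default 10).
    rt_window_min : maximum |ΔRT| from the component seed, in minutes
        (default 2.5; a deviation, not a full width).
    min_intensity : intensity threshold for seeding a component and for a
        presence call (default 5e6 counts).
    derep_tol_ppm : accurate-mass match tolerance for dereplication and
        known-compound monitoring (default 3 ppm).
    """

    mz_tol_ppm: float = 10.0
    rt_window_min: float = 2.5
    min_intensity: float = 5e6
    derep_tol_ppm: float = 3.0

    def __post_init__(self) -> None:
        for name in ("mz_tol_ppm", "rt_window_min", "min_intensity", "derep_tol_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Component:
    """A cross-sample LC-HRMS entity.

    ``mz`` is the intensity-weighted mean m/z of the member features, ``rt``
    the intensity-weighted RT centroid. ``intensities`` maps sample_id to the
    summed member intensity (samples with no member simply absent, i.e. 0);
    ``raw_intensities`` preserves the pre-normalization values, which presence
    calls are made on.
    """

    component_id: str
    mz: float
    rt: float
    intensities: Mapping[str, float]
    raw_intensities: Mapping[str, float]
    n_features: int

    def intensity_in(self, sample_id: str) -> float:
        return self.intensities.get(sample_id, 0.0)


_FEATURE_COLUMNS = ("sample_id", "mz", "rt_min", "intensity")


def _as_arrays(features: pd.DataFrame):
    missing = [c for c in _FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    mz = features["mz"].to_numpy(dtype=float)
    rt = features["rt_min"].to_numpy(dtype=float)
    inten = features["intensity"].to_numpy(dtype=float)
    samples = features["sample_id"].astype(str).to_numpy()
    if (mz <= 0).any():
        raise ValueError("feature m/z must be positive")
    if (inten < 0).any():
        raise ValueError("feature intensity must be non-negative")
    return samples, mz, rt, inten


def detect_components(features: pd.DataFrame, config: ScreenConfig = ScreenConfig()) -> list[Component]:
    """Greedy seeded componentization across all samples.

    Repeatedly take the globally most intense unassigned feature with
    intensity >= ``min_intensity`` as a seed, and assign to it every
    unassigned feature — from any sample, at any intensity — whose m/z lies
    within ``mz_tol_ppm`` of the seed m/z and whose RT lies within
    ``rt_window_min`` of the seed RT. Sub-threshold features that never join
    a component are discarded. Seed order ties are broken by (lower m/z,
    earlier RT, sample_id), so the output is order-deterministic.
    """
    if len(features) == 0:
        return []
    samples, mz, rt, inten = _as_arrays(features)
    n = len(mz)
    # seed priority: intensity desc, then m/z, RT, sample_id ascending
    order = np.lexsort((samples, rt, mz, -inten))
    assigned = np.zeros(n, dtype=bool)
    components: list[Component] = []
    n_assigned = 0
    for idx in order:
        if assigned[idx] or inten[idx] < config.min_intensity:
            continue
        seed_mz, seed_rt = mz[idx], rt[idx]
        members = (
            ~assigned
            & (np.abs(mz - seed_mz) <= seed_mz * config.mz_tol_ppm * 1e-6)
            & (np.abs(rt - seed_rt) <= config.rt_window_min)
        )
        members[idx] = True
        assigned |= members
        midx = np.flatnonzero(members)
        n_assigned += len(midx)
        w = inten[midx]
        wsum = w.sum()
        if wsum > 0:
            mz_consensus = float(np.average(mz[midx], weights=w))
            rt_centroid = float(np.average(rt[midx], weights=w))
        else:  # all members zero intensity; fall back to seed values
            mz_consensus, rt_centroid = float(seed_mz), float(seed_rt)
        per_sample: dict[str, float] = {}
        for j in midx:
            per_sample[samples[j]] = per_sample.get(samples[j], 0.0) + float(inten[j])
        components.append(
            Component(
                component_id=f"C{len(components) + 1:04d}",
                mz=mz_consensus,
                rt=rt_centroid,
                intensities=dict(per_sample),
                raw_intensities=dict(per_sample),
                n_features=len(midx),
            )
        )
    # conservation: every feature is assigned to exactly one component or discarded
    assert n_assigned == int(assigned.sum()) and n_assigned + int((~assigned).sum()) == n
    return components


def sample_tics(features: pd.DataFrame) -> dict[str, float]:
    """Per-sample total ion current: sum of all raw feature intensities."""
    if len(features) == 0:
        return {}
    samples, _, _, inten = _as_arrays(features)
    tics: dict[str, float] = {}
    for s, x in zip(samples, inten):
        tics[s] = tics.get(s, 0.0) + float(x)
    return tics


def normalize_tic(components: Sequence[Component], tics: Mapping[str, float]) -> list[Component]:
    """Scale each sample's component intensities by (mean TIC) / (sample TIC).

    Within-sample intensity ratios are preserved exactly; raw intensities are
    retained unchanged on every component.

    Raises
    ------
    ValueError
        If any sample has a non-positive TIC (named in the message).
    """
    if not tics:
        if components:
            raise ValueError("no TICs supplied for non-empty component list")
        return []
    for sample, tic in tics.items():
        if tic <= 0:
            raise ValueError(f"sample {sample!r} has non-positive TIC ({tic})")
    mean_tic = sum(tics.values()) / len(tics)
    factors = {s: mean_tic / t for s, t in tics.items()}
    out = []
    for comp in components:
        scaled = {}
        for sample, value in comp.raw_intensities.items():
            if sample not in factors:
                raise ValueError(f"sample {sample!r} missing from TIC table")
            scaled[sample] = value * factors[sample]
        out.append(replace(comp, intensities=scaled))
    return out


def presence_calls(
    components: Sequence[Component],
    design: Mapping[str, str],
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Strain-level presence matrix (strains x components, boolean).

    A component is present in a sample iff its raw (pre-normalization)
    intensity is >= ``min_intensity``, and present in a strain iff it is
    present in every one of that strain's samples (biological and technical
    replicates pooled) — the strictest replicate rule, chosen to keep the
    uniqueness filter conservative.

    Raises
    ------
    KeyError
        If a component carries a sample_id absent from the design.
    """
    strains = sorted(set(design.values()))
    strain_samples: dict[str, list[str]] = {s: [] for s in strains}
    for sample, strain in design.items():
        strain_samples[strain].append(sample)
    data = {}
    for comp in components:
        for sample in comp.raw_intensities:
            if sample not in design:
                raise KeyError(f"sample {sample!r} not in the design table")
        data[comp.component_id] = [
            all(
                comp.raw_intensities.get(sample, 0.0) >= config.min_intensity
                for sample in strain_samples[strain]
            )
            for strain in strains
        ]
    return pd.DataFrame(data, index=pd.Index(strains, name="strain"), dtype=bool)


def _check_strains(presence: pd.DataFrame, names: Iterable[str]) -> None:
    unknown = [s for s in names if s not in presence.index]
    if unknown:
        raise ValueError(f"unknown strain name(s): {unknown}")


def uniqueness_filter(
    presence: pd.DataFrame,
    target_strain: str,
    control_strains: Sequence[str],
) -> list[str]:
    """Component ids present in the target strain and in no control strain."""
    _check_strains(presence, [target_strain, *control_strains])
    if target_strain in control_strains:
        raise ValueError("target strain cannot also be a control")
    if len(presence.columns) == 0:
        return []
    keep = presence.loc[target_strain]
    for strain in control_strains:
        keep = keep & ~presence.loc[strain]
    return [cid for cid in presence.columns if bool(keep[cid])]


@dataclass(frozen=True)
class ScreenResult:
    """Uniqueness verdicts for a target strain plus the decoy FDR estimate.

    ``fdr_estimate`` is the mean pseudo-target unique count over all decoy
    reruns divided by max(1, target unique count); ``presence_pattern`` maps
    each unique component to the set of strains it is present in (always
    exactly the target under the filter's definition, kept for audit).
    """

    target_strain: str
    unique_components: tuple[str, ...]
    fdr_estimate: float
    pseudo_target_counts: Mapping[str, int]
    presence_pattern: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def decoy_fdr(
    presence: pd.DataFrame,
    target_strain: str,
    control_strains: Sequence[str],
) -> ScreenResult:
    """Uniqueness screen with a decoy-based false-discovery estimate.

    Each control strain is rerun as a pseudo-target against the remaining
    controls, with the real target excluded throughout so a genuine unique
    compound cannot inflate the null. The FDR estimate is the mean
    pseudo-target unique count over max(1, the real target's unique count).

    Raises
    ------
    ValueError
        If fewer than two control strains are supplied.
    """
    controls = list(control_strains)
    if len(controls) < 2:
        raise ValueError("decoy FDR needs at least two control strains")
    unique = uniqueness_filter(presence, target_strain, controls)
    pseudo: dict[str, int] = {}
    for decoy in controls:
        others = [s for s in controls if s != decoy]
        pseudo[decoy] = len(uniqueness_filter(presence, decoy, others))
    fdr = float(np.mean(list(pseudo.values()))) / max(1, len(unique))
    pattern = {
        cid: tuple(presence.index[presence[cid]]) for cid in unique
    }
    return ScreenResult(
        target_strain=target_strain,
        unique_components=tuple(unique),
        fdr_estimate=fdr,
        pseudo_target_counts=pseudo,
        presence_pattern=pattern,
    )


def monitor_known_compounds(
    components: Sequence[Component],
    known: Sequence[CompoundRecord],
    config: ScreenConfig = ScreenConfig(),
    sample_ids: Sequence[str] | None = None,
    adducts: Mapping[str, tuple[float, int]] = DEFAULT_ADDUCTS,
    cv_threshold: float = 0.5,
) -> pd.DataFrame:
    """Consistency report for known housekeeping compounds.

    For each known compound, components matching any configured adduct m/z
    within ``derep_tol_ppm`` are pooled; the report gives the fraction of
    samples in which the pooled raw intensity clears the presence threshold,
    and the coefficient of variation (sample SD over mean, ddof=1) of the
    normalized intensity across detected samples. Compounds with CV above
    ``cv_threshold`` or with no detection are flagged — a quick monitor for
    highly perturbed runs.
    """
    if sample_ids is None:
        ids: set[str] = set()
        for comp in components:
            ids.update(comp.raw_intensities)
        sample_ids = sorted(ids)
    rows = []
    for rec in known:
        matched = []
        for comp in components:
            for label in adducts:
                theo = adduct_mz(rec.monoisotopic_mass, label, adducts)
                if abs(ppm_error(comp.mz, theo)) <= config.derep_tol_ppm:
                    matched.append(comp)
                    break
        raw = {s: sum(c.raw_intensities.get(s, 0.0) for c in matched) for s in sample_ids}
        norm = {s: sum(c.intensities.get(s, 0.0) for c in matched) for s in sample_ids}
        detected = [s for s in sample_ids if raw[s] >= config.min_intensity]
        frac = len(detected) / len(sample_ids) if sample_ids else 0.0
        if len(detected) >= 2:
            values = np.array([norm[s] for s in detected])
            cv = float(values.std(ddof=1) / values.mean()) if values.mean() > 0 else float("nan")
        elif len(detected) == 1:
            cv = 0.0
        else:
            cv = float("nan")
        flagged = frac == 0.0 or (np.isfinite(cv) and cv > cv_threshold)
        rows.append(
            {
                "compound": rec.name,
                "n_components": len(matched),
                "detection_fraction": frac,
                "cv_normalized": cv,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)
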