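"""Synthetic BOLD cohorts with known ground truth.

Generates parcellated "brains" and per-subject 4D BOLD series with the
statistical structure the downstream analysis assumes: stimulus-evoked
responses (HRF-convolved condition regressors scaled by per-region
amplitudes and per-group multipliers), planted inter-regional coupling
(shared latent fluctuations injected into region pairs, with channel sign),
and Gaussian noise at both the region and the voxel level.

The default geometry is desk-scale (16 x 16 x 8 grid, 20 regions, 975
effective volumes); the full acquisition geometry (64 x 64 x 22, 1950
volumes at TR 2 s) is supported but not the default, since every property
the analysis is tested on is geometry-independent.

Amplitudes and noise are expressed in percent signal change relative to a
constant baseline (default 100), so a planted amplitude of 3 means a 3 %
peak response.
"""

from __future__ import annotations

import hashlib
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import HRFParams, Paradigm, design_matrix
from .preprocess import VolumeSeries

__all__ = [
    "AtlasLabels",
    "CouplingSpec",
    "EffectSpec",
    "SubjectData",
    "Cohort",
    "make_atlas",
    "simulate_subject",
    "simulate_region_timecourses",
    "simulate_cohort",
]

DEFAULT_GRID = (16, 16, 8)
DEFAULT_N_REGIONS = 20
#: analyzed ofMRI group sizes (controls vs. optogenetically activated)
DEFAULT_GROUP_SIZES = {"control": 5, "activated": 9}


@dataclass(frozen=True)
class AtlasLabels:
    """Integer label volume (0 = background) plus a region id -> name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        ids = self.region_ids
        if len(ids) and (ids[0] != 1 or np.any(np.diff(ids) != 1)):
            raise ValueError("region ids must be contiguous from 1")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def voxels_of(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels.ravel() == region_id)


@dataclass(frozen=True)
class CouplingSpec:
    """A planted coupling between two regions.

    ``channel`` is "positive" (shared latent added with the same sign to
    both regions) or "negative" (opposite signs). ``strength`` maps group
    name -> latent amplitude in percent signal change; groups absent from
    the map get 0.
    """

    region_a: int
    region_b: int
    channel: str
    strength: dict[str, float]

    def __post_init__(self) -> None:
        if self.channel not in ("positive", "negative"):
            raise ValueError("channel must be 'positive' or 'negative'")
        for g, s in self.strength.items():
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"coupling strength for {g!r} outside [-1, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect specification for a synthetic cohort.

    Parameters
    ----------
    amplitudes : {region_id: {condition: percent signal change}}
    group_multipliers : {group: {condition: multiplier}} or {group: scalar}
    couplings : planted inter-regional couplings
    noise_sd : percent signal change; applied independently at the region
        and the voxel level
    activation_probability : {region_id: probability}; per subject, each
        region's amplitude is Bernoulli-gated with this probability
        (default 1)
    baseline : raw signal baseline
    """

    amplitudes: dict[int, dict[str, float]] = field(default_factory=dict)
    group_multipliers: dict[str, object] = field(default_factory=dict)
    couplings: tuple[CouplingSpec, ...] = ()
    noise_sd: float = 0.2
    activation_probability: dict[int, float] = field(default_factory=dict)
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for r, conds in self.amplitudes.items():
            for c, a in conds.items():
                if not np.isfinite(a):
                    raise ValueError(f"amplitude for region {r}/{c} not finite")
        object.__setattr__(self, "couplings", tuple(self.couplings))

    def multiplier(self, group: str, condition: str) -> float:
        m = self.group_multipliers.get(group, 1.0)
        if isinstance(m, dict):
            return float(m.get(condition, 1.0))
        return float(m)


@dataclass
class SubjectData:
    """One simulated subject: the volume series plus its ground truth."""

    subject: str
    group: str
    seed: int
    series: VolumeSeries
    truth: dict

    def region_truth_timecourses(self) -> pd.DataFrame | None:
        tc = self.truth.get("region_signals")
        return None if tc is None else pd.DataFrame(tc)


@dataclass
class Cohort:
    groups: dict[str, list[SubjectData]]
    seed: int

    @property
    def subjects(self) -> list[SubjectData]:
        return [s for grp in self.groups.values() for s in grp]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for s in sorted(self.subjects, key=lambda s: s.subject):
            h.update(s.subject.encode())
            h.update(np.ascontiguousarray(s.series.data).tobytes())
        return h.hexdigest()


def make_atlas(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    n_regions: int = DEFAULT_N_REGIONS,
    seed: int = 0,
) -> AtlasLabels:
    """Parcellate a brain-like ellipsoidal mask into compact contiguous
    regions by multi-source breadth-first region growing from seeded voxels.
    """
    shape = tuple(int(s) for s in grid_shape)
    coords = np.indices(shape).reshape(3, -1).T
    center = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) / 2.0, 1.0)
    mask_flat = (((coords - center) / semi) ** 2).sum(axis=1) <= 1.0
    mask_idx = np.flatnonzero(mask_flat)
    if n_regions < 1 or n_regions > mask_idx.size:
        raise ValueError(
            f"cannot place {n_regions} regions in a mask of {mask_idx.size} voxels"
        )
    rng = np.random.default_rng(seed)
    seeds = rng.choice(mask_idx, size=n_regions, replace=False)

    labels = np.zeros(int(np.prod(shape)), dtype=np.int32)
    inmask = np.zeros(int(np.prod(shape)), dtype=bool)
    inmask[mask_idx] = True
    strides = np.array(
        [shape[1] * shape[2], shape[2], 1]
    )  # flat-index steps along x, y, z
    queue: deque[int] = deque()
    for rid, s in enumerate(seeds, start=1):
        labels[s] = rid
        queue.append(int(s))
    while queue:
        v = queue.popleft()
        cz = v % shape[2]
        cy = (v // shape[2]) % shape[1]
        cx = v // (shape[1] * shape[2])
        for axis, c, lim in ((0, cx, shape[0]), (1, cy, shape[1]), (2, cz, shape[2])):
            for d in (-1, 1):
                if 0 <= c + d < lim:
                    w = v + d * strides[axis]
                    if inmask[w] and labels[w] == 0:
                        labels[w] = labels[v]
                        queue.append(int(w))
    labels = labels.reshape(shape)
    names = {i: f"region_{i:03d}" for i in range(1, n_regions + 1)}
    return AtlasLabels(labels=labels, names=names)


def _condition_regressors(
    paradigm: Paradigm, hrf: HRFParams | None
) -> dict[str, np.ndarray]:
    design = design_matrix(paradigm, hrf, drift=False)
    return {k: design.column(k) for k in design.stim_columns}


def _region_signals(
    paradigm: Paradigm,
    region_ids: np.ndarray,
    spec: EffectSpec,
    group: str,
    rng: np.random.Generator,
    hrf: HRFParams | None,
) -> tuple[np.ndarray, dict]:
    """Region x time percent-signal-change matrix plus ground truth."""
    t = paradigm.n_volumes
    regressors = _condition_regressors(paradigm, hrf)
    n = len(region_ids)
    pct = np.zeros((n, t))
    # Bernoulli gating of per-region responsiveness (draw in fixed region
    # order for determinism)
    gates = {}
    for rid in region_ids:
        p = spec.activation_probability.get(int(rid), 1.0)
        gates[int(rid)] = bool(rng.random() < p) if p < 1.0 else True
    effective = {}
    for i, rid in enumerate(region_ids):
        conds = spec.amplitudes.get(int(rid), {})
        eff = {}
        for cond, amp in conds.items():
            if cond not in regressors:
                continue
            a = amp * spec.multiplier(group, cond) * (1.0 if gates[int(rid)] else 0.0)
            pct[i] += a * regressors[cond]
            eff[cond] = a
        effective[int(rid)] = eff
    # shared latent fluctuations for planted couplings
    index = {int(rid): i for i, rid in enumerate(region_ids)}
    planted = []
    for c in spec.couplings:
        s = c.strength.get(group, 0.0)
        z = rng.standard_normal(t)  # draw even when s == 0: group-independent streams
        if s == 0.0:
            continue
        sign = 1.0 if c.channel == "positive" else -1.0
        pct[index[c.region_a]] += s * z
        pct[index[c.region_b]] += sign * s * z
        planted.append(
            {"pair": (c.region_a, c.region_b), "channel": c.channel, "strength": s}
        )
    if spec.noise_sd > 0:
        pct += rng.standard_normal((n, t)) * spec.noise_sd
    truth = {
        "group": group,
        "gates": gates,
        "effective_amplitudes": effective,
        "planted_couplings": planted,
        "regressors": {k: v for k, v in regressors.items()},
    }
    return pct, truth


def simulate_region_timecourses(
    paradigm: Paradigm,
    n_regions: int,
    spec: EffectSpec,
    group: str,
    seed: int,
    hrf: HRFParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Region-level fast path: simulate the region x time signal matrix
    directly (raw signal units), skipping voxel expansion.

    Identical model to :func:`simulate_subject` minus the voxel-averaging
    step; intended for statistical suites where only region time courses
    enter the analysis.
    """
    region_ids = np.arange(1, n_regions + 1)
    rng = np.random.default_rng(seed)
    pct, truth = _region_signals(paradigm, region_ids, spec, group, rng, hrf)
    data = spec.baseline * (1.0 + pct / 100.0)
    df = pd.DataFrame(data, index=region_ids)
    df.index.name = "region"
    return df, truth


def simulate_subject(
    paradigm: Paradigm,
    atlas: AtlasLabels,
    spec: EffectSpec,
    group: str,
    seed: int,
    hrf: HRFParams | None = None,
    subject: str = "sub-01",
    voxel_size: float = 0.234,
) -> SubjectData:
    """Simulate one subject's 4D BOLD series.

    Region signal = baseline x (1 + percent/100) where percent combines the
    gated stimulus response, planted shared latents, and region-level noise;
    each voxel adds independent Gaussian noise of the same sd on top of its
    region's signal. Background voxels hold the constant baseline.
    """
    missing = [
        r for r in spec.amplitudes if r not in set(map(int, atlas.region_ids))
    ]
    if missing:
        raise ValueError(f"effect spec references unknown regions {missing}")
    rng = np.random.default_rng(seed)
    region_ids = atlas.region_ids
    pct, truth = _region_signals(paradigm, region_ids, spec, group, rng, hrf)
    t = paradigm.n_volumes
    region_signal = spec.baseline * (1.0 + pct / 100.0)

    flat_labels = atlas.labels.ravel()
    nvox = flat_labels.size
    data = np.full((nvox, t), spec.baseline, dtype=np.float64)
    for i, rid in enumerate(region_ids):
        vox = np.flatnonzero(flat_labels == rid)
        data[vox] = region_signal[i]
        if spec.noise_sd > 0:
            data[vox] += (
                rng.standard_normal((vox.size, t))
                * spec.noise_sd
                * spec.baseline
                / 100.0
            )
    series = VolumeSeries(
        data=data.reshape(atlas.labels.shape + (t,)),
        tr=paradigm.tr,
        voxel_size=voxel_size,
    )
    truth["region_signals"] = {
        int(rid): region_signal[i] for i, rid in enumerate(region_ids)
    }
    return SubjectData(
        subject=subject, group=group, seed=seed, series=series, truth=truth
    )


def simulate_cohort(
    paradigm: Paradigm,
    atlas: AtlasLabels,
    spec: EffectSpec,
    group_sizes: dict[str, int] | None = None,
    seed: int = 0,
    hrf: HRFParams | None = None,
) -> Cohort:
    """Simulate a cohort; per-subject seeds are derived deterministically
    from the cohort seed via a seed sequence."""
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    for g, n in group_sizes.items():
        if n < 1:
            raise ValueError(f"group {g!r} must have >= 1 subject")
    n_total = sum(group_sizes.values())
    child_seeds = [
        int(s)
        for s in np.random.SeedSequence(seed).generate_state(n_total) % (2**31)
    ]
    groups: dict[str, list[SubjectData]] = {}
    k = 0
    for g in sorted(group_sizes):
        groups[g] = []
        for j in range(group_sizes[g]):
            sub = simulate_subject(
                paradigm,
                atlas,
                spec,
                group=g,
                seed=child_seeds[k],
                hrf=hrf,
                subject=f"sub-{g}-{j + 1:02d}",
            )
            groups[g].append(sub)
            k += 1
    return Cohort(groups=groups, seed=seed)


def cohort_manifest(cohort: Cohort) -> pd.DataFrame:
    """Tabular cohort manifest (subject, group, seed)."""
    rows = [
        {"subject": s.subject, "group": s.group, "seed": s.seed}
        for s in cohort.subjects
    ]
    return pd.DataFrame(rows)


def write_subject(sub: SubjectData, atlas: AtlasLabels, outdir) -> dict:
    """Write NIfTI series + atlas labels + JSON ground-truth sidecar."""
    import nibabel as nib
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag([sub.series.voxel_size] * 3 + [1.0])
    bold = outdir / f"{sub.subject}_bold.nii"
    nib.Nifti1Image(sub.series.data.astype(np.float32), aff).to_filename(str(bold))
    atl = outdir / "atlas_labels.nii"
    nib.Nifti1Image(atlas.labels.astype(np.int16), aff).to_filename(str(atl))
    truth = {
        k: v
        for k, v in sub.truth.items()
        if k not in ("region_signals", "regressors")
    }
    sidecar = outdir / f"{sub.subject}_truth.json"
    sidecar.write_text(json.dumps(truth, default=str, indent=1))
    return {"bold": str(bold), "atlas": str(atl), "truth": str(sidecar)}
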