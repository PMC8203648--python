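"""Atlas labeling, region time courses, event-related averaging, and
group comparison of BOLD response amplitudes.

Region time courses average the significantly activated voxels of each
atlas region; regions are carried into group analyses only when their
activation probability across subjects and conditions reaches a threshold
(the selection rule that reduced 196 atlas regions to 100 in the reference
protocol). Event-related averages align windows of fixed length (pre +
stimulation + post timepoints) on event onsets, reference each window to
its pre-stimulus baseline, and average across the event presentations of
one condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import Paradigm
from .preprocess import VolumeSeries
from .glm import ActivationMask
from .synthetic import AtlasLabels

__all__ = [
    "RegionTimecourses",
    "ERAProfile",
    "AmplitudeMap",
    "region_timecourses",
    "activation_probability",
    "event_related_average",
    "compare_era_groups",
    "amplitude_map",
]


@dataclass
class RegionTimecourses:
    """Region x time matrix of mean signal over active voxels.

    ``data`` rows are region ids (only regions with at least one active
    voxel); ``n_active`` counts the voxels averaged per region; ``units``
    is "raw" or "percent" depending on upstream preprocessing.
    """

    data: pd.DataFrame
    n_active: pd.Series
    tr: float
    subject: str = ""
    units: str = "raw"
    omitted_regions: tuple[int, ...] = ()

    @property
    def regions(self) -> list[int]:
        return list(self.data.index)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class ERAProfile:
    """Event-related average profiles, region x window timepoint.

    The window is ``pre`` timepoints before onset, the stimulation
    timepoints, and ``post`` timepoints after; values are percent signal
    change referenced to each window's pre-period mean.
    """

    data: pd.DataFrame
    pre: int
    stim: int
    post: int
    n_events: int
    subject: str = ""

    @property
    def window(self) -> int:
        return self.pre + self.stim + self.post


@dataclass
class AmplitudeMap:
    """Maximum BOLD amplitude (percent signal change magnitude) per voxel
    or region, within one condition's event windows."""

    values: np.ndarray | pd.Series
    condition: str


def region_timecourses(
    series: VolumeSeries,
    mask: ActivationMask | np.ndarray,
    atlas: AtlasLabels,
    predictor: str | None = None,
    units: str = "raw",
    subject: str = "",
) -> RegionTimecourses:
    """Average the time courses of each region's significantly activated
    voxels. Regions with no active voxel are omitted and listed."""
    if atlas.labels.shape != series.data.shape[:3]:
        raise ValueError(
            f"atlas geometry {atlas.labels.shape} does not match series "
            f"{series.data.shape[:3]}"
        )
    if isinstance(mask, ActivationMask):
        if predictor is None:
            if len(mask.masks) != 1:
                raise ValueError("predictor required for multi-predictor masks")
            predictor = next(iter(mask.masks))
        m = mask.mask(predictor)
    else:
        m = np.asarray(mask, dtype=bool)
    flat = series.data.reshape(-1, series.n_volumes)
    labels = atlas.labels.ravel()
    active = m.ravel()
    rows, counts, omitted = {}, {}, []
    for rid in atlas.region_ids:
        vox = np.flatnonzero((labels == rid) & active)
        if vox.size == 0:
            omitted.append(int(rid))
            continue
        rows[int(rid)] = flat[vox].mean(axis=0)
        counts[int(rid)] = int(vox.size)
    data = pd.DataFrame(rows).T
    data.index.name = "region"
    return RegionTimecourses(
        data=data,
        n_active=pd.Series(counts, dtype=int),
        tr=series.tr,
        subject=subject,
        units=units,
        omitted_regions=tuple(omitted),
    )


def activation_probability(
    activity_flags: pd.DataFrame, threshold: float = 0.5
) -> list[int]:
    """Select regions by activation probability.

    ``activity_flags`` is a boolean table with one row per subject x
    condition entry and one column per region (True where the region had at
    least one significantly active voxel). A region is selected when the
    fraction of flagged entries is >= ``threshold``. Returns region ids in
    fixed (sorted) order.
    """
    if activity_flags.shape[0] < 1:
        raise ValueError("need at least one subject entry")
    prob = activity_flags.astype(float).mean(axis=0)
    return sorted(int(r) for r in prob.index[prob >= threshold])


def _onset_index(onset: float, tr: float) -> int:
    return int(round(onset / tr))


def event_related_average(
    tc: RegionTimecourses,
    paradigm: Paradigm,
    condition: str,
    pre: int = 10,
    post: int = 15,
) -> ERAProfile:
    """Average stimulus-locked windows across one condition's events.

    Windows span ``pre`` timepoints before the onset volume, the
    stimulation period, and ``post`` timepoints after it. Each window is
    referenced to the mean of its pre period: raw-unit inputs are converted
    to percent signal change ((x - base)/base * 100), percent-unit inputs
    are baseline-subtracted. Events whose window would be truncated are
    excluded with a warning.
    """
    events = paradigm.events_of_kind(condition)
    if not events:
        raise ValueError(f"paradigm has no {condition!r} events")
    stim = int(round(events[0].duration / tc.tr))
    t = tc.n_timepoints
    x = tc.data.to_numpy()
    windows = []
    n_used = 0
    for e in events:
        i0 = _onset_index(e.onset, tc.tr)
        lo, hi = i0 - pre, i0 + stim + post
        if lo < 0 or hi > t:
            warnings.warn(
                f"{condition} event at {e.onset:g}s excluded: window "
                f"[{lo}, {hi}) outside the time course",
                stacklevel=2,
            )
            continue
        w = x[:, lo:hi]
        base = w[:, :pre].mean(axis=1, keepdims=True)
        if tc.units == "percent":
            windows.append(w - base)
        else:
            windows.append((w - base) / base * 100.0)
        n_used += 1
    if not windows:
        raise ValueError("no usable event windows")
    prof = np.mean(windows, axis=0)
    cols = np.arange(-pre, stim + post)
    data = pd.DataFrame(prof, index=tc.data.index, columns=cols)
    return ERAProfile(
        data=data, pre=pre, stim=stim, post=post, n_events=n_used,
        subject=tc.subject,
    )


def _era_table(profiles: list[ERAProfile], group: str) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(profiles):
        sub = p.subject or f"{group}-{i}"
        for rid in p.data.index:
            for tp, val in p.data.loc[rid].items():
                rows.append(
                    {"subject": sub, "group": group, "region": int(rid),
                     "time": int(tp), "value": float(val)}
                )
    return pd.DataFrame(rows)


def compare_era_groups(
    group_a: list[ERAProfile],
    group_b: list[ERAProfile],
    alpha: float = 0.05,
    label_a: str = "control",
    label_b: str = "treated",
) -> pd.DataFrame:
    """Compare event-related averages between two groups, per region.

    For each region present in at least two subjects of each group, a
    one-factor repeated-measures ANOVA over the window timepoints with
    group as between-subject factor (mixed ANOVA: within = timepoint,
    between = group), Tukey HSD post hoc on the group factor, and
    Bonferroni correction across regions. Reports the difference of means
    over the stimulation window with its SEM and the direction of change
    ("enhanced" when the second group exceeds the first, "reduced"
    otherwise).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two subjects per group")
    import pingouin as pg

    long = pd.concat(
        [_era_table(group_a, label_a), _era_table(group_b, label_b)],
        ignore_index=True,
    )
    # regions present in both groups with >= 2 subjects each (pairwise
    # exclusion of regions missing from a subject's time courses)
    counts = (
        long.groupby(["region", "group"])["subject"].nunique().unstack(fill_value=0)
    )
    regions = [
        int(r)
        for r in counts.index
        if counts.loc[r].get(label_a, 0) >= 2 and counts.loc[r].get(label_b, 0) >= 2
    ]
    results = []
    stim0 = 0  # stimulation starts at window time 0
    for rid in regions:
        d = long[long.region == rid]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aov = pg.mixed_anova(
                    data=d, dv="value", within="time", subject="subject",
                    between="group",
                )
                tukey = pg.pairwise_tukey(
                    data=d.groupby(["subject", "group"], as_index=False)["value"].mean(),
                    dv="value", between="group",
                )
            p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
            p_group = float(aov.loc[aov.Source == "group", p_col].iloc[0])
            t_col = "p_tukey" if "p_tukey" in tukey.columns else "p-tukey"
            p_tukey = float(tukey[t_col].iloc[0])
        except Exception:
            # degenerate input (e.g. zero within-group variance): no test
            p_group = p_tukey = np.nan
        stim_win = d[d.time >= stim0]
        means = stim_win.groupby(["group", "subject"])["value"].mean()
        ma, mb = means[label_a], means[label_b]
        diff = float(mb.mean() - ma.mean())
        sem = float(np.sqrt(ma.sem() ** 2 + mb.sem() ** 2))
        results.append(
            {
                "region": rid,
                "p_group": p_group,
                "p_tukey": p_tukey,
                "diff_mean": diff,
                "sem_diff": sem,
                "direction": "enhanced" if diff > 0 else ("reduced" if diff < 0 else "none"),
            }
        )
    out = pd.DataFrame(results)
    if len(out):
        m = len(out)
        out["p_bonf"] = np.minimum(out["p_group"] * m, 1.0)
        out["significant"] = out["p_bonf"] <= alpha
    return out.set_index("region") if len(out) else out


def amplitude_map(
    source: VolumeSeries | RegionTimecourses,
    paradigm: Paradigm,
    condition: str,
    lag: float = 16.0,
    pre: int = 10,
) -> AmplitudeMap:
    """Maximum percent-signal-change magnitude within one condition's event
    windows (onset to stimulus end + ``lag`` seconds of hemodynamic delay).

    Percent change is referenced per event to the mean of the ``pre``
    timepoints before onset (raw units) or baseline-subtracted (percent
    units); constant signals map to 0.
    """
    events = paradigm.events_of_kind(condition)
    if not events:
        raise ValueError(f"paradigm has no {condition!r} events")
    if isinstance(source, RegionTimecourses):
        x = source.data.to_numpy()
        tr, units, t = source.tr, source.units, source.n_timepoints
        index = source.data.index
    else:
        x = source.data.reshape(-1, source.n_volumes)
        tr, units, t = source.tr, "raw", source.n_volumes
        index = None
    best = np.zeros(x.shape[0])
    for e in events:
        i0 = _onset_index(e.onset, tr)
        hi = min(t, i0 + int(np.ceil((e.duration + lag) / tr)))
        lo = max(0, i0 - pre)
        if i0 <= lo or hi <= i0:
            continue
        base = x[:, lo:i0].mean(axis=1, keepdims=True)
        w = x[:, i0:hi]
        if units == "percent":
            dev = np.abs(w - base)
        else:
            dev = np.abs((w - base) / base * 100.0)
        best = np.maximum(best, dev.max(axis=1))
    if index is not None:
        values: np.ndarray | pd.Series = pd.Series(best, index=index)
    else:
        values = best.reshape(source.data.shape[:3])
    return AmplitudeMap(values=values, condition=condition)
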