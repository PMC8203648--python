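"""Stimulation paradigms and HRF-convolved design matrices.

A paradigm is an ordered list of typed stimulation events (peripheral heat,
optogenetic laser, or simultaneous laser-heat co-stimulation) together with
the acquisition timing (repetition time and number of volumes). Each event
has a ramped onset followed by a plateau, mirroring a Peltier heating device
that needs a few seconds to reach its target temperature.

Design matrices are built by sampling a trapezoidal stimulus function per
event kind, convolving it with a two-gamma hemodynamic response function
(HRF), and evaluating at the volume acquisition times. One regressor per
stimulus kind, plus constant and linear drift columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gamma as _gamma

__all__ = [
    "StimKind",
    "StimulusEvent",
    "Paradigm",
    "HRFParams",
    "DesignMatrix",
    "build_costim_paradigm",
    "build_wt_heat_paradigm",
    "two_gamma_hrf",
    "design_matrix",
]

#: fixed regressor ordering for reproducible design matrices
KIND_ORDER = ("heat", "laser", "costim")


class StimKind(str, Enum):
    HEAT = "heat"
    LASER = "laser"
    COSTIM = "costim"


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulation event.

    Parameters
    ----------
    kind : {"heat", "laser", "costim"}
    onset : float
        Seconds from scan start.
    ramp : float
        Linear rise time to plateau amplitude, seconds.
    plateau : float
        Time at plateau amplitude, seconds.
    magnitude : float
        Unitless label (e.g. target temperature in deg C).
    """

    kind: str
    onset: float
    ramp: float = 5.0
    plateau: float = 15.0
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KIND_ORDER:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.ramp < 0:
            raise ValueError("event ramp must be >= 0")
        if self.plateau <= 0:
            raise ValueError("event plateau must be > 0")

    @property
    def duration(self) -> float:
        return self.ramp + self.plateau

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Paradigm:
    """Ordered stimulation events plus acquisition timing."""

    events: tuple[StimulusEvent, ...]
    tr: float
    n_volumes: int

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        onsets = [e.onset for e in events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for a, b in zip(events, events[1:]):
            if b.onset < a.end:
                raise ValueError(
                    f"events overlap: {a.kind} at {a.onset:g}s runs to "
                    f"{a.end:g}s, past the {b.kind} onset at {b.onset:g}s"
                )
        for e in events:
            if e.end > self.duration:
                raise ValueError(
                    f"{e.kind} event at onset {e.onset:g}s ends at {e.end:g}s, "
                    f"beyond the scan duration of {self.duration:g}s"
                )

    @property
    def duration(self) -> float:
        """Scan duration in seconds (tr x n_volumes)."""
        return self.tr * self.n_volumes

    @property
    def kinds(self) -> tuple[str, ...]:
        """Distinct event kinds present, in declared order."""
        present = {e.kind for e in self.events}
        return tuple(k for k in KIND_ORDER if k in present)

    def events_of_kind(self, kind: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind == kind)

    def shifted(self, by: float) -> "Paradigm":
        """Return a copy with all onsets shifted by ``by`` seconds."""
        return replace(
            self,
            events=tuple(replace(e, onset=e.onset + by) for e in self.events),
        )

    def with_timing(self, tr: float, n_volumes: int) -> "Paradigm":
        return replace(self, tr=tr, n_volumes=n_volumes)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "ramp_s": [e.ramp for e in self.events],
                "plateau_s": [e.plateau for e in self.events],
                "magnitude": [e.magnitude for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tr: float, n_volumes: int) -> "Paradigm":
        events = tuple(
            StimulusEvent(
                kind=row.kind,
                onset=float(row.onset_s),
                ramp=float(row.ramp_s),
                plateau=float(row.plateau_s),
                magnitude=float(row.magnitude),
            )
            for row in df.itertuples()
        )
        return cls(events=events, tr=tr, n_volumes=n_volumes)

    @classmethod
    def from_tsv(cls, path, tr: float, n_volumes: int) -> "Paradigm":
        return cls.from_frame(pd.read_csv(path, sep="\t"), tr, n_volumes)


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF parameters.

    The response is the difference of two gamma-density lobes, a positive
    response lobe peaking at ``time_to_peak`` and an undershoot lobe peaking
    at ``undershoot_peak``, scaled down by ``ratio``. Each lobe is a gamma
    density with its mode pinned at the requested peak time
    (shape = peak/dispersion + 1, scale = dispersion).
    """

    time_to_peak: float = 5.0
    undershoot_peak: float = 15.0
    ratio: float = 6.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0 or self.undershoot_peak <= 0:
            raise ValueError("peak times must be > 0")
        if self.time_to_peak >= self.undershoot_peak:
            raise ValueError("time_to_peak must precede undershoot_peak")
        if self.ratio <= 0:
            raise ValueError("response/undershoot ratio must be > 0")
        if self.dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersion parameters must be > 0")


def two_gamma_hrf(t, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the two-gamma HRF at times ``t`` (seconds).

    Zero for t <= 0 (causality); normalized to unit peak.
    """
    params = params or HRFParams()
    t = np.asarray(t, dtype=float)
    a1 = params.time_to_peak / params.dispersion + 1.0
    a2 = params.undershoot_peak / params.undershoot_dispersion + 1.0
    h = _gamma.pdf(t, a=a1, scale=params.dispersion) - (
        _gamma.pdf(t, a=a2, scale=params.undershoot_dispersion) / params.ratio
    )
    h = np.where(t <= 0, 0.0, h)
    # unit-peak normalization; peak value depends only on params, so compute
    # it on a dense reference grid once per call
    ref = np.arange(0.0, params.undershoot_peak * 3, 0.01)
    peak = np.max(
        _gamma.pdf(ref, a=a1, scale=params.dispersion)
        - _gamma.pdf(ref, a=a2, scale=params.undershoot_dispersion) / params.ratio
    )
    return h / peak


@dataclass(frozen=True)
class DesignMatrix:
    """Per-volume regressor amplitudes, one column per stimulus kind present
    plus constant and linear drift."""

    matrix: np.ndarray  # (n_volumes, n_columns)
    columns: tuple[str, ...]
    stim_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))


def build_costim_paradigm(
    n_heat: int = 16,
    interval: float = 100.0,
    stim_duration: float = 20.0,
    ramp: float = 5.0,
    tr: float = 4.0,
    n_volumes: int = 975,
    initial_rest: float = 100.0,
    magnitude: float = 50.0,
) -> Paradigm:
    """Build the laser-heat co-stimulation paradigm.

    ``n_heat`` heat-class stimuli of ``stim_duration`` seconds each
    (``ramp`` seconds linear ramp, remainder plateau); every 2nd heat
    stimulus is combined with simultaneous laser application (co-stimulation),
    and one laser-only stimulus is interspersed between consecutive
    heat-class stimuli. The onset-to-onset interval between consecutive
    stimuli of any kind is ``interval`` seconds.

    Defaults reproduce a 65-min protocol: 16 heat-class events (8 heat-only,
    8 co-stimulation) interleaved with 16 laser-only events at a 100 s
    stimulus interval.
    """
    if n_heat < 0:
        raise ValueError("n_heat must be >= 0")
    if interval < stim_duration:
        raise ValueError("stimulus interval must be >= stimulus duration")
    plateau = stim_duration - ramp
    events: list[StimulusEvent] = []
    for i in range(n_heat):
        # heat-class event i (1-based): every 2nd becomes co-stimulation
        heat_kind = "costim" if (i + 1) % 2 == 0 else "heat"
        onset = initial_rest + 2 * i * interval
        events.append(
            StimulusEvent(heat_kind, onset, ramp, plateau, magnitude)
        )
        # one interleaved laser-only stimulus after each heat-class event
        events.append(
            StimulusEvent("laser", onset + interval, ramp, plateau, 1.0)
        )
    return Paradigm(events=tuple(events), tr=tr, n_volumes=n_volumes)


def build_wt_heat_paradigm(
    temperatures: list[float] | tuple[float, ...] = (40.0, 45.0, 50.0, 55.0),
    n_sets: int = 3,
    initial_rest: float = 120.0,
    stim_duration: float = 20.0,
    interval: float = 220.0,
    ramp: float = 5.0,
    tr: float = 4.0,
    n_volumes: int = 750,
) -> Paradigm:
    """Build the wild-type ascending-heat paradigm.

    ``n_sets`` repetitions of the ascending temperature list (defaults:
    innocuous 40/45 deg C and noxious 50/55 deg C), starting after
    ``initial_rest`` seconds of rest, with a constant onset-to-onset
    ``interval`` (default 3 min 40 s) within a 50-min session.
    """
    temperatures = list(temperatures)
    if not temperatures:
        raise ValueError("temperature list must be non-empty")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if list(temperatures) != sorted(temperatures) or len(set(temperatures)) != len(
        temperatures
    ):
        raise ValueError("temperatures must be strictly ascending")
    plateau = stim_duration - ramp
    events = []
    i = 0
    for _ in range(n_sets):
        for temp in temperatures:
            events.append(
                StimulusEvent(
                    "heat", initial_rest + i * interval, ramp, plateau, temp
                )
            )
            i += 1
    return Paradigm(events=tuple(events), tr=tr, n_volumes=n_volumes)


def _stimulus_function(
    paradigm: Paradigm, kind: str, tgrid: np.ndarray
) -> np.ndarray:
    """Trapezoidal stimulus function for one event kind on a dense grid."""
    s = np.zeros_like(tgrid)
    for e in paradigm.events_of_kind(kind):
        rel = tgrid - e.onset
        if e.ramp > 0:
            up = np.clip(rel / e.ramp, 0.0, 1.0)
        else:
            up = (rel >= 0).astype(float)
        up[rel > e.duration] = 0.0
        s = s + up
    return s


def design_matrix(
    paradigm: Paradigm,
    params: HRFParams | None = None,
    dt: float = 0.1,
    drift: bool = True,
) -> DesignMatrix:
    """HRF-convolved design matrix sampled at the volume times.

    Per event kind present in the paradigm, a trapezoidal boxcar (linear
    ramp, then plateau at amplitude 1) is convolved with the two-gamma HRF on
    a dense grid of step ``dt`` and evaluated at t = i * tr. Constant and
    linear drift columns are appended when ``drift`` is true.

    Results are memoized per (paradigm, params, dt, drift); callers must
    treat the returned matrix as read-only.
    """
    return _design_matrix_cached(paradigm, params or HRFParams(), dt, drift)


@lru_cache(maxsize=64)
def _design_matrix_cached(
    paradigm: Paradigm, params: HRFParams, dt: float, drift: bool
) -> DesignMatrix:
    n = paradigm.n_volumes
    vol_times = np.arange(n) * paradigm.tr
    tgrid = np.arange(0.0, paradigm.duration + params.undershoot_peak * 3, dt)
    hker = two_gamma_hrf(tgrid - tgrid[0], params)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for kind in paradigm.kinds:
        s = _stimulus_function(paradigm, kind, tgrid)
        x = signal.fftconvolve(s, hker)[: tgrid.size] * dt
        # normalize so an isolated long plateau would reach the HRF's
        # unit-peak block response; keeps regressor amplitude comparable
        # across dt choices
        scale = np.sum(hker) * dt
        x = x / scale if scale > 0 else x
        idx = np.clip(np.round(vol_times / dt).astype(int), 0, tgrid.size - 1)
        cols.append(x[idx])
        names.append(kind)
    stim_names = tuple(names)
    if drift:
        cols.append(np.ones(n))
        names.append("constant")
        lin = np.arange(n, dtype=float)
        lin = lin - lin.mean()
        cols.append(lin / max(lin.max(), 1.0))
        names.append("drift")
    if not cols:
        mat = np.empty((n, 0))
    else:
        mat = np.column_stack(cols)
    return DesignMatrix(matrix=mat, columns=tuple(names), stim_columns=stim_names)
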