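"""Preprocessing of 4D BOLD series on motion-free data.

Covers the temporal-resampling and filtering contracts of the analysis:
discarding initial volumes (MR saturation), pairwise volume averaging
(TR 2000 ms -> TR_eff 4000 ms), in-plane spatial Gaussian smoothing, and
high-pass temporal filtering (linear detrend + removal of the lowest FFT
cycles) followed by temporal Gaussian smoothing.

Motion correction and affine registration to a reference anatomy are
interface placeholders that return their input unchanged: synthetic data is
generated pre-registered and motion-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .paradigm import Paradigm

__all__ = [
    "VolumeSeries",
    "discard_initial",
    "pairwise_average",
    "spatial_smooth",
    "temporal_filter",
    "to_percent_change",
    "motion_correct",
    "register_to_reference",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VolumeSeries:
    """4D BOLD data (x, y, z, t) with repetition time and voxel geometry."""

    data: np.ndarray
    tr: float
    voxel_size: float = 0.234
    provenance: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one volume")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _step(self, data: np.ndarray, op: str, **params) -> "VolumeSeries":
        rec = {"op": op, **params}
        return replace(
            self, data=data, provenance=self.provenance + (rec,)
        )

    def write_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), aff)
        img.header.set_zooms((self.voxel_size,) * 3 + (self.tr,))
        img.to_filename(str(path))
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"tr": self.tr, "provenance": list(self.provenance)}, fh)

    @classmethod
    def read_nifti(cls, path, tr: float | None = None) -> "VolumeSeries":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if tr is None and len(zooms) > 3 else tr
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            tr=float(tr),
            voxel_size=float(zooms[0]),
        )


def discard_initial(
    series: VolumeSeries, n: int, paradigm: Paradigm | None = None
):
    """Drop the first ``n`` volumes (MR saturation).

    When a paradigm is supplied, a copy with onsets re-referenced by
    ``-n * tr`` (and matching volume count) is returned alongside.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n} of {series.n_volumes} volumes"
        )
    out = series._step(series.data[..., n:], "discard_initial", n=n)
    if paradigm is None:
        return out
    shifted = paradigm.shifted(-n * series.tr).with_timing(
        paradigm.tr, out.n_volumes
    )
    return out, shifted


def pairwise_average(series: VolumeSeries) -> VolumeSeries:
    """Average every two consecutive volumes, doubling the repetition time
    (e.g. TR 2000 ms -> TR_eff 4000 ms). A trailing odd volume is dropped."""
    t = series.n_volumes
    if t < 2:
        raise ValueError("pairwise averaging needs at least two volumes")
    t2 = t // 2
    d = series.data[..., : 2 * t2]
    avg = 0.5 * (d[..., 0::2] + d[..., 1::2])
    out = series._step(avg, "pairwise_average", dropped_trailing=bool(t % 2))
    return replace(out, tr=series.tr * 2.0)


def spatial_smooth(series: VolumeSeries, fwhm_vox: float = 2.0) -> VolumeSeries:
    """Per-volume in-plane (x, y) Gaussian smoothing, reflective boundary.

    ``fwhm_vox`` is the kernel full width at half maximum in voxels.
    """
    if fwhm_vox <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm_vox * FWHM_TO_SIGMA
    sm = ndimage.gaussian_filter(
        series.data, sigma=(sigma, sigma, 0.0, 0.0), mode="reflect"
    )
    return series._step(sm, "spatial_smooth", fwhm_vox=fwhm_vox)


def _removal_basis(t: int, n_cycles: int) -> np.ndarray:
    """Orthonormal basis of the removed components: full linear trend
    (intercept and slope) plus sine/cosine pairs for the ``n_cycles``
    lowest nonzero frequencies."""
    cols = [np.ones(t)]
    lin = np.arange(t, dtype=float)
    lin -= lin.mean()
    cols.append(lin)
    x = np.arange(t)
    for k in range(1, n_cycles + 1):
        cols.append(np.cos(2 * np.pi * k * x / t))
        cols.append(np.sin(2 * np.pi * k * x / t))
    basis = np.column_stack(cols)
    q, _ = np.linalg.qr(basis)
    return q


def temporal_filter(
    series: VolumeSeries, n_cycles: int = 9, smooth_fwhm_s: float = 12.0
) -> VolumeSeries:
    """High-pass filter plus temporal smoothing, per voxel.

    Removes the linear trend (intercept and slope) and the ``n_cycles``
    lowest-frequency Fourier components, applies Gaussian temporal smoothing
    of ``smooth_fwhm_s`` seconds FWHM (as a transfer function in the rfft
    domain), and finally re-projects out the removed basis so the output
    stays exactly orthogonal to it. The output fluctuates around zero;
    convert to percent signal change *before* filtering when baselined
    units are needed downstream.
    """
    t = series.n_volumes
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if t < 4 or n_cycles >= t // 2:
        raise ValueError("series too short for the requested filter")
    q = _removal_basis(t, n_cycles)
    flat = series.data.reshape(-1, t)
    # project out removed basis
    resid = flat - (flat @ q) @ q.T
    if smooth_fwhm_s > 0:
        sigma = smooth_fwhm_s * FWHM_TO_SIGMA
        freqs = np.fft.rfftfreq(t, d=series.tr)
        transfer = np.exp(-2.0 * (np.pi * sigma * freqs) ** 2)
        resid = np.fft.irfft(np.fft.rfft(resid, axis=1) * transfer, n=t, axis=1)
        resid = resid - (resid @ q) @ q.T
    out = resid.reshape(series.data.shape)
    return series._step(
        out, "temporal_filter", n_cycles=n_cycles, smooth_fwhm_s=smooth_fwhm_s
    )


def to_percent_change(
    series: VolumeSeries, paradigm: Paradigm | None = None, n_baseline: int | None = None
) -> VolumeSeries:
    """Convert to percent signal change per voxel.

    Baseline = per-voxel mean over the pre-stimulation rest volumes (those
    acquired before the first event onset), or over ``n_baseline`` initial
    volumes when given explicitly. Falls back to the whole-series mean when
    no rest period is available.
    """
    t = series.n_volumes
    if n_baseline is None:
        if paradigm is not None and paradigm.events:
            n_baseline = int(paradigm.events[0].onset // series.tr)
        else:
            n_baseline = t
    n_baseline = max(1, min(n_baseline, t))
    base = series.data[..., :n_baseline].mean(axis=3, keepdims=True)
    if np.any(base == 0):
        raise ValueError("zero baseline voxel; cannot form percent change")
    pct = (series.data - base) / base * 100.0
    return series._step(pct, "to_percent_change", n_baseline=n_baseline)


def motion_correct(series: VolumeSeries) -> VolumeSeries:
    """Identity placeholder: synthetic data is motion-free. Accepts
    externally motion-corrected input."""
    return series._step(series.data, "motion_correct", method="identity")


def register_to_reference(series: VolumeSeries, reference=None) -> VolumeSeries:
    """Identity placeholder: synthetic data is generated pre-registered.
    Accepts externally registered input."""
    return series._step(series.data, "register_to_reference", method="identity")
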