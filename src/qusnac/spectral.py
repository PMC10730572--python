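"""Spectral quantitative-ultrasound estimation.

Implements the reference-phantom method: tapered per-line periodograms over
sliding analysis windows (10 wavelengths square, 94 % overlap by default),
normalization by a reference phantom of known backscatter and attenuation,
linear-regression spectral parameters (midband fit MBF, spectral slope SS,
0-MHz intercept SI) over the -6 dB band, spectral-difference attenuation
estimation (ACE), and spherical Gaussian scatterer-model (SGM) inversion for
average scatterer diameter (ASD) and average acoustic concentration (AAC).

Units: frequencies Hz internally (MHz in fitted slopes), depths metres
internally (cm in attenuation terms), ASD in micrometres, AAC in dB relative
to the reference phantom's acoustic concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .frame import RFFrame
from .phantom import (
    _REFERENCE_DENSITY,
    _REFERENCE_RADIUS,
    REFERENCE_ATTENUATION_DB_MHZ_CM,
)

__all__ = [
    "EmptyGridError",
    "NormalizationError",
    "SpectralFitError",
    "DegenerateScattererSizeError",
    "AttenuationEstimationError",
    "WindowGrid",
    "NormalizedSpectrum",
    "ParametricMap",
    "AttenuationEstimate",
    "PowerSpectrum",
    "build_window_grid",
    "window_power_spectrum",
    "reference_spectra",
    "ReferenceSpectraCache",
    "normalize_spectrum",
    "fit_spectral_params",
    "estimate_ace",
    "fit_sgm",
    "gaussian_bsc",
    "build_parametric_maps",
    "REFERENCE_BSC_A_EFF",
    "REFERENCE_BSC_N_AC",
    "SGM_C0",
    "SGM_EXPONENT",
]


class EmptyGridError(ValueError):
    """ROI too small to hold a single analysis window."""


class NormalizationError(ValueError):
    """Reference spectrum unusable (non-positive inside the band)."""


class SpectralFitError(ValueError):
    """Too few usable frequency points for a spectral line fit."""


class DegenerateScattererSizeError(ValueError):
    """Measured backscatter shows no Gaussian decay (non-negative slope)."""


class AttenuationEstimationError(ValueError):
    """Insufficient or collinear depths for spectral-difference estimation."""


#: Gaussian form-factor exponent constant of the spherical scatterer model.
SGM_EXPONENT = 0.827
#: Overall SGM amplitude constant; fixed to one so acoustic concentration is
#: expressed relative to the reference phantom's (AAC = 0 dB for the
#: reference itself).
SGM_C0 = 1.0
#: Effective radius (m) assigned to the reference phantom's backscatter model.
REFERENCE_BSC_A_EFF = _REFERENCE_RADIUS
#: Minimum Gaussian decay (|slope| of ln BSC - 4 ln f vs k^2) considered
#: measurable; corresponds to an effective scatterer diameter of 1 um, far
#: below anything resolvable in the 3-8 MHz band.
_MIN_DECAY = SGM_EXPONENT * (0.5e-6) ** 2
#: Acoustic concentration assigned to the reference phantom (relative units).
REFERENCE_BSC_N_AC = 1.0

_NFFT = 256  # zero-padded FFT length for window periodograms


def gaussian_bsc(
    frequencies: np.ndarray,
    a_eff: float,
    n_ac: float,
    sound_speed: float = 1540.0,
    c0: float = SGM_C0,
) -> np.ndarray:
    """Spherical-Gaussian-model backscatter coefficient.

    ``BSC(f) = c0 * k^4 * a_eff^6 * n_ac * exp(-0.827 k^2 a_eff^2)`` with
    ``k = 2 pi f / c``.
    """
    k = 2.0 * np.pi * np.asarray(frequencies, dtype=float) / sound_speed
    return c0 * k**4 * a_eff**6 * n_ac * np.exp(-SGM_EXPONENT * (k * a_eff) ** 2)


def reference_bsc_db(frequencies: np.ndarray, sound_speed: float = 1540.0) -> np.ndarray:
    """dB backscatter model of the calibration reference phantom."""
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(
            gaussian_bsc(frequencies, REFERENCE_BSC_A_EFF, REFERENCE_BSC_N_AC, sound_speed)
        )


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowGrid:
    """Sliding analysis-window layout over an ROI.

    Window blocks are ``block_axial`` samples x ``block_lateral`` lines
    (10 wavelengths in physical units), laid out on a rectangular grid with
    steps ``step_axial`` / ``step_lateral`` over the ROI bounding box;
    ``inside`` marks grid cells whose block lies fully inside the ROI.
    """

    block_axial: int
    block_lateral: int
    step_axial: int
    step_lateral: int
    ax_offsets: np.ndarray
    lat_offsets: np.ndarray
    inside: np.ndarray
    overlap_fraction: float
    axial_sample_spacing: float
    line_spacing: float
    depth_origin: float

    @property
    def shape(self) -> tuple:
        return (self.ax_offsets.size, self.lat_offsets.size)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    def window_depths(self) -> np.ndarray:
        """Depth (m) of each axial row's window centre."""
        return self.depth_origin + (self.ax_offsets + self.block_axial / 2.0) * self.axial_sample_spacing


def build_window_grid(
    roi_mask: np.ndarray,
    frame: RFFrame,
    overlap: float = 0.94,
) -> WindowGrid:
    """Lay out 10-wavelength analysis windows with the given overlap.

    Block size is 10 wavelengths at the transducer centre frequency, rounded
    to whole samples/lines; the step is the non-overlapping fraction of the
    block (minimum one sample/line).  Only blocks lying fully inside the ROI
    are retained.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != frame.samples.shape:
        raise ValueError("roi_mask shape must match frame samples")
    if not mask.any():
        raise EmptyGridError("empty ROI")
    t = frame.transducer
    extent = 10.0 * t.wavelength
    block_ax = max(int(round(extent / frame.axial_sample_spacing)), 2)
    block_lat = max(int(round(extent / frame.line_spacing)), 2)
    step_ax = max(int(round((1.0 - overlap) * block_ax)), 1)
    step_lat = max(int(round((1.0 - overlap) * block_lat)), 1)

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size < block_ax or cols.size < block_lat:
        raise EmptyGridError("ROI smaller than one analysis window")
    ax_offsets = np.arange(rows[0], rows[-1] - block_ax + 2, step_ax)
    lat_offsets = np.arange(cols[0], cols[-1] - block_lat + 2, step_lat)

    # Integral image for "block fully inside ROI" tests.
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    a0 = ax_offsets[:, None]
    l0 = lat_offsets[None, :]
    counts = (
        ii[a0 + block_ax, l0 + block_lat]
        - ii[a0, l0 + block_lat]
        - ii[a0 + block_ax, l0]
        + ii[a0, l0]
    )
    inside = counts == block_ax * block_lat
    if not inside.any():
        raise EmptyGridError("no analysis window fits fully inside the ROI")
    return WindowGrid(
        block_axial=block_ax,
        block_lateral=block_lat,
        step_axial=step_ax,
        step_lateral=step_lat,
        ax_offsets=ax_offsets,
        lat_offsets=lat_offsets,
        inside=inside,
        overlap_fraction=overlap,
        axial_sample_spacing=frame.axial_sample_spacing,
        line_spacing=frame.line_spacing,
        depth_origin=frame.depth_origin,
    )


# ---------------------------------------------------------------------------
# Power spectra
# ---------------------------------------------------------------------------


class PowerSpectrum(NamedTuple):
    frequencies: np.ndarray
    power: np.ndarray
    valid: bool


def window_power_spectrum(
    block: np.ndarray, sampling_rate: float, nfft: int = _NFFT
) -> PowerSpectrum:
    """Hann-tapered per-line periodograms averaged across a block's lines.

    ``block`` is (axial samples x lines).  All-zero blocks are flagged
    invalid (excluded downstream).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.size == 0:
        raise ValueError("empty block")
    n = block.shape[0]
    nfft = max(nfft, n)
    taper = np.hanning(n)
    spec = np.fft.rfft(block * taper[:, None], n=nfft, axis=0)
    power = (np.abs(spec) ** 2).mean(axis=1) / np.sum(taper**2)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)
    return PowerSpectrum(freqs, power, valid=bool(block.any()))


def _line_periodograms(
    samples: np.ndarray, ax_offsets: np.ndarray, block_axial: int, nfft: int
) -> np.ndarray:
    """Per (axial offset, line) tapered periodograms: (n_ax, n_lines, n_freq)."""
    taper = np.hanning(block_axial)
    norm = np.sum(taper**2)
    segs = np.stack([samples[a : a + block_axial] for a in ax_offsets], axis=0)
    segs = segs * taper[None, :, None]
    spec = np.fft.rfft(segs, n=nfft, axis=1)
    return (np.abs(spec) ** 2).transpose(0, 2, 1) / norm


def _grid_spectra(frame: RFFrame, grid: WindowGrid, nfft: int = _NFFT) -> tuple[np.ndarray, np.ndarray]:
    """Average periodogram of every grid window: (n_ax, n_lat, n_freq)."""
    c0 = int(grid.lat_offsets.min())
    c1 = int(grid.lat_offsets.max()) + grid.block_lateral
    per_line = _line_periodograms(frame.samples[:, c0:c1], grid.ax_offsets, grid.block_axial, nfft)
    csum = np.concatenate(
        [np.zeros((per_line.shape[0], 1, per_line.shape[2])), np.cumsum(per_line, axis=1)], axis=1
    )
    l0 = grid.lat_offsets - c0
    spectra = (csum[:, l0 + grid.block_lateral] - csum[:, l0]) / grid.block_lateral
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.sampling_rate)
    return freqs, spectra


class ReferenceSpectraCache:
    """Depth-resolved reference spectra with per-offset memoization.

    Wraps a set of reference-phantom frames; row spectra (averaged over
    lines and frames) are computed on demand per axial window offset and
    cached, so repeated extractions over a patient cohort reuse them.
    ``line_stride`` subsamples the lines entering the average (the average
    over a few hundred statistically independent lines is already smooth).
    """

    def __init__(self, frames, block_axial: int, nfft: int = _NFFT, line_stride: int = 1):
        self.frames = [frames] if isinstance(frames, RFFrame) else list(frames)
        self.block_axial = int(block_axial)
        self.nfft = int(nfft)
        self.line_stride = int(line_stride)
        self.frequencies = np.fft.rfftfreq(self.nfft, d=1.0 / self.frames[0].sampling_rate)
        self._cache: dict[int, np.ndarray] = {}

    def rows(self, ax_offsets: np.ndarray) -> np.ndarray:
        missing = [int(a) for a in ax_offsets if int(a) not in self._cache]
        if missing:
            acc = None
            for fr in self.frames:
                per_line = _line_periodograms(
                    fr.samples[:, :: self.line_stride],
                    np.asarray(missing),
                    self.block_axial,
                    self.nfft,
                )
                mean = per_line.mean(axis=1)
                acc = mean if acc is None else acc + mean
            acc /= len(self.frames)
            for i, a in enumerate(missing):
                self._cache[a] = acc[i]
        return np.stack([self._cache[int(a)] for a in ax_offsets])


def reference_spectra(
    frames: list[RFFrame] | RFFrame,
    ax_offsets: np.ndarray,
    block_axial: int,
    nfft: int = _NFFT,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth-resolved reference-phantom spectra, averaged over all lines.

    One spectrum per axial window offset, averaged across every line of every
    supplied reference frame (a physical-phantom calibration sweep).
    Returns (freqs, spectra) with spectra shaped (n_ax, n_freq).
    """
    if isinstance(frames, RFFrame):
        frames = [frames]
    acc = None
    for fr in frames:
        per_line = _line_periodograms(fr.samples, np.asarray(ax_offsets), block_axial, nfft)
        mean = per_line.mean(axis=1)
        acc = mean if acc is None else acc + mean
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frames[0].sampling_rate)
    return freqs, acc / len(frames)


# ---------------------------------------------------------------------------
# Normalization and spectral fits
# ---------------------------------------------------------------------------


@dataclass
class NormalizedSpectrum:
    """Reference-normalized backscatter spectrum (dB) of one window.

    ``values_db`` is the estimated backscatter coefficient in dB:
    ``10 log10(S_sample / S_reference) + 10 log10(BSC_ref)`` plus the
    attenuation-difference compensation ``4 (alpha_s - alpha_r) f z``.
    ``usable_band`` is the -6 dB band of the reference spectrum clipped to
    the transducer band.
    """

    frequencies: np.ndarray
    values_db: np.ndarray
    usable_band: tuple
    depth: float

    def band_mask(self) -> np.ndarray:
        lo, hi = self.usable_band
        return (self.frequencies >= lo) & (self.frequencies <= hi)


def usable_band_from_reference(
    freqs: np.ndarray, ref_power: np.ndarray, band: tuple = (3.0e6, 8.0e6)
) -> tuple:
    """-6 dB band of the reference spectrum, clipped to the nominal band."""
    clip = (freqs >= band[0]) & (freqs <= band[1])
    if not clip.any() or np.all(ref_power[clip] <= 0):
        raise NormalizationError("reference spectrum non-positive in the nominal band")
    sub = np.where(clip, ref_power, -np.inf)
    peak_idx = int(np.argmax(sub))
    thresh = ref_power[peak_idx] * 10.0 ** (-6.0 / 10.0)
    above = (ref_power >= thresh) & clip
    # contiguous run around the peak
    lo = peak_idx
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi + 1 < freqs.size and above[hi + 1]:
        hi += 1
    return (float(freqs[lo]), float(freqs[hi]))


def normalize_spectrum(
    sample_power: np.ndarray,
    ref_power: np.ndarray,
    frequencies: np.ndarray,
    depth: float,
    ace_sample: float,
    ace_reference: float = REFERENCE_ATTENUATION_DB_MHZ_CM,
    sound_speed: float = 1540.0,
    band: tuple = (3.0e6, 8.0e6),
    bsc_ref_db: np.ndarray | None = None,
) -> NormalizedSpectrum:
    """Reference-phantom normalization of one window's power spectrum.

    ``depth`` in metres; ``ace_*`` in dB/MHz/cm.  The attenuation-difference
    compensation restores ``4 (alpha_s - alpha_r)(f) z`` dB of round-trip
    loss (point compensation at the window depth).
    """
    freqs = np.asarray(frequencies, dtype=float)
    usable = usable_band_from_reference(freqs, ref_power, band)
    in_band = (freqs >= usable[0]) & (freqs <= usable[1])
    if np.any(ref_power[in_band] <= 0):
        raise NormalizationError("reference spectrum non-positive inside the usable band")
    if bsc_ref_db is None:
        bsc_ref_db = reference_bsc_db(freqs, sound_speed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * np.log10(sample_power / ref_power)
    comp_db = 4.0 * (ace_sample - ace_reference) * (freqs / 1e6) * (depth * 100.0)
    values = ratio_db + bsc_ref_db + comp_db
    return NormalizedSpectrum(freqs, values, usable, depth)


class SpectralParams(NamedTuple):
    mbf_db: float
    ss_db_mhz: float
    si_db: float


def fit_spectral_params(spectrum: NormalizedSpectrum) -> SpectralParams:
    """MBF / SS / SI by ordinary least squares over the usable band.

    SS is the line's slope (dB/MHz), SI its value at 0 MHz, MBF its value at
    the centre of the usable band.
    """
    m = spectrum.band_mask() & np.isfinite(spectrum.values_db)
    if m.sum() < 3:
        raise SpectralFitError("fewer than 3 usable frequency points")
    f_mhz = spectrum.frequencies[m] / 1e6
    y = spectrum.values_db[m]
    slope, intercept = np.polyfit(f_mhz, y, 1)
    f_mid = 0.5 * (spectrum.usable_band[0] + spectrum.usable_band[1]) / 1e6
    return SpectralParams(
        mbf_db=float(intercept + slope * f_mid),
        ss_db_mhz=float(slope),
        si_db=float(intercept),
    )


# ---------------------------------------------------------------------------
# Attenuation (spectral difference method)
# ---------------------------------------------------------------------------


@dataclass
class AttenuationEstimate:
    """Attenuation coefficient estimate with fit diagnostics."""

    ace_db_mhz_cm: float
    per_freq_alpha: np.ndarray = field(default=None, repr=False)
    frequencies: np.ndarray = field(default=None, repr=False)
    depth_fit_rms_db: float = float("nan")
    line_fit_rms: float = float("nan")


def estimate_ace(
    sample_spectra: np.ndarray,
    ref_spectra: np.ndarray,
    depths: np.ndarray,
    frequencies: np.ndarray,
    alpha_reference: float = REFERENCE_ATTENUATION_DB_MHZ_CM,
    band: tuple = (3.0e6, 8.0e6),
) -> AttenuationEstimate:
    """Spectral-difference attenuation estimate.

    For each in-band frequency the dB ratio ``10 log10(S_s / S_r)`` is fitted
    linearly against depth (cm); the slope equals ``-4 (alpha_s - alpha_r)``
    at that frequency.  ``alpha_s(f)`` is then fitted through the origin
    against frequency (MHz) to yield ACE in dB/MHz/cm.
    """
    S = np.asarray(sample_spectra, dtype=float)
    R = np.asarray(ref_spectra, dtype=float)
    depths = np.asarray(depths, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    if S.shape != R.shape or S.shape[0] != depths.size:
        raise ValueError("sample/reference spectra and depths must align")
    if np.unique(depths).size < 3:
        raise AttenuationEstimationError("need at least 3 distinct depths")
    m = (freqs >= band[0]) & (freqs <= band[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * np.log10(S[:, m] / R[:, m])
    good = np.all(np.isfinite(ratio_db), axis=0)
    if good.sum() < 2:
        raise AttenuationEstimationError("too few usable frequencies")
    ratio_db = ratio_db[:, good]
    f_mhz = freqs[m][good] / 1e6
    z_cm = depths * 100.0
    A = np.stack([z_cm, np.ones_like(z_cm)], axis=1)
    coef, *_ = np.linalg.lstsq(A, ratio_db, rcond=None)
    slopes = coef[0]  # dB/cm per frequency
    resid = ratio_db - A @ coef
    alpha_f = alpha_reference * f_mhz - slopes / 4.0  # alpha_s(f), dB/cm
    ace = float(np.sum(f_mhz * alpha_f) / np.sum(f_mhz**2))
    line_resid = alpha_f - ace * f_mhz
    return AttenuationEstimate(
        ace_db_mhz_cm=ace,
        per_freq_alpha=alpha_f,
        frequencies=f_mhz * 1e6,
        depth_fit_rms_db=float(np.sqrt(np.mean(resid**2))),
        line_fit_rms=float(np.sqrt(np.mean(line_resid**2))),
    )


# ---------------------------------------------------------------------------
# Spherical Gaussian scatterer model
# ---------------------------------------------------------------------------


class SgmFit(NamedTuple):
    asd_um: float
    aac_db: float


def fit_sgm(
    bsc: np.ndarray,
    frequencies: np.ndarray,
    sound_speed: float = 1540.0,
    c0: float = SGM_C0,
) -> SgmFit:
    """Invert the spherical Gaussian model by linearized regression.

    ``ln BSC - 4 ln f`` is regressed against ``k^2``; the slope gives the
    effective radius (ASD is its diameter, in um) and the intercept the
    acoustic concentration (AAC in dB) after removing the ``c0 a^6`` term.
    """
    bsc = np.asarray(bsc, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    ok = np.isfinite(bsc) & (bsc > 0) & (freqs > 0)
    if ok.sum() < 4:
        raise SpectralFitError("need BSC > 0 at >= 4 in-band frequencies")
    f = freqs[ok]
    k2 = (2.0 * np.pi * f / sound_speed) ** 2
    y = np.log(bsc[ok]) - 4.0 * np.log(f)
    slope, intercept = np.polyfit(k2, y, 1)
    if slope >= -_MIN_DECAY:
        raise DegenerateScattererSizeError("no measurable Gaussian decay")
    a_eff = float(np.sqrt(-slope / SGM_EXPONENT))
    n_ac = np.exp(intercept - 4.0 * np.log(2.0 * np.pi / sound_speed)) / (c0 * a_eff**6)
    return SgmFit(asd_um=2.0 * a_eff * 1e6, aac_db=float(10.0 * np.log10(n_ac)))


def _fit_sgm_batch(
    bsc_db: np.ndarray, freqs: np.ndarray, sound_speed: float, c0: float = SGM_C0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SGM inversion for many windows sharing one frequency grid.

    ``bsc_db`` is (n_windows, n_freq) in dB.  Windows with non-negative decay
    slope are flagged NaN.
    """
    f = np.asarray(freqs, dtype=float)
    k2 = (2.0 * np.pi * f / sound_speed) ** 2
    ln_bsc = bsc_db * (np.log(10.0) / 10.0)
    y = ln_bsc - 4.0 * np.log(f)[None, :]
    x = k2 - k2.mean()
    denom = np.sum(x**2)
    slope = (y @ x) / denom
    intercept = y.mean(axis=1) - slope * k2.mean()
    bad = slope >= -_MIN_DECAY
    with np.errstate(invalid="ignore"):
        a_eff = np.sqrt(-slope / SGM_EXPONENT)
        n_ac = np.exp(intercept - 4.0 * np.log(2.0 * np.pi / sound_speed)) / (c0 * a_eff**6)
        asd = 2.0 * a_eff * 1e6
        aac = 10.0 * np.log10(n_ac)
    asd[bad] = np.nan
    aac[bad] = np.nan
    return asd, aac


# ---------------------------------------------------------------------------
# Parametric maps
# ---------------------------------------------------------------------------

MAP_PARAMETERS = ("MBF", "SS", "SI", "ASD", "AAC")
_MAP_UNITS = {"MBF": "dB", "SS": "dB/MHz", "SI": "dB", "ASD": "um", "AAC": "dB"}


@dataclass
class ParametricMap:
    """One QUS parameter rasterized on the window grid (NaN = missing)."""

    parameter: str
    values: np.ndarray
    grid: WindowGrid
    units: str = ""

    def mean(self) -> float:
        """Mean over non-missing raster cells."""
        if np.all(np.isnan(self.values)):
            return float("nan")
        return float(np.nanmean(self.values))


def build_parametric_maps(
    frame: RFFrame,
    roi_mask: np.ndarray,
    reference: "list[RFFrame] | RFFrame | tuple",
    overlap: float = 0.94,
    ace: float | None = None,
    band: tuple = (3.0e6, 8.0e6),
    nfft: int = _NFFT,
) -> tuple[dict, AttenuationEstimate]:
    """Construct MBF/SS/SI/ASD/AAC parametric maps over an ROI.

    ``reference`` is either reference RF frame(s) acquired with the same
    transducer or a precomputed ``(freqs, spectra_by_axial_offset)`` pair
    from :func:`reference_spectra`.  When ``ace`` is None the tumour
    attenuation is first estimated from the ROI itself (spectral difference
    against the reference); otherwise the supplied scalar is used for the
    normalization compensation.

    Returns (maps, attenuation estimate); windows whose spectra are unusable
    are stored as missing, and a quality warning is emitted when more than
    half the ROI's windows are flagged.
    """
    grid = build_window_grid(roi_mask, frame, overlap)
    freqs, spectra = _grid_spectra(frame, grid, nfft)
    if isinstance(reference, ReferenceSpectraCache):
        if reference.block_axial != grid.block_axial or reference.nfft != nfft:
            raise ValueError("reference cache built for a different window geometry")
        ref_spec = reference.rows(grid.ax_offsets)
    elif isinstance(reference, tuple) and not isinstance(reference, RFFrame):
        rfreqs, ref_spec = reference
        if rfreqs.size != freqs.size or not np.allclose(rfreqs, freqs):
            raise ValueError("precomputed reference spectra use a different frequency grid")
        if ref_spec.shape[0] != grid.ax_offsets.size:
            raise ValueError("precomputed reference spectra do not match the window grid rows")
    else:
        _, ref_spec = reference_spectra(reference, grid.ax_offsets, grid.block_axial, nfft)

    depths = grid.window_depths()
    n_ax, n_lat = grid.shape
    inside = grid.inside

    # --- tumour attenuation from ROI row-average spectra
    att: AttenuationEstimate
    if ace is None:
        rows = np.flatnonzero(inside.any(axis=1))
        if rows.size < 3:
            raise AttenuationEstimationError("ROI spans fewer than 3 window depths")
        row_mean = np.stack(
            [spectra[r, inside[r]].mean(axis=0) for r in rows], axis=0
        )
        att = estimate_ace(row_mean, ref_spec[rows], depths[rows], freqs, band=band)
    else:
        att = AttenuationEstimate(ace_db_mhz_cm=float(ace))

    bsc_ref = reference_bsc_db(freqs, frame.transducer.sound_speed)
    comp_rate = 4.0 * (att.ace_db_mhz_cm - REFERENCE_ATTENUATION_DB_MHZ_CM) * (freqs / 1e6)

    maps = {p: np.full((n_ax, n_lat), np.nan) for p in MAP_PARAMETERS}
    n_flagged = 0
    for r in range(n_ax):
        cells = np.flatnonzero(inside[r])
        if cells.size == 0:
            continue
        usable = usable_band_from_reference(freqs, ref_spec[r], band)
        bm = (freqs >= usable[0]) & (freqs <= usable[1])
        if bm.sum() < 4:
            n_flagged += cells.size
            continue
        S = spectra[r, cells][:, bm]
        Rp = ref_spec[r, bm]
        ok = np.all(S > 0, axis=1)
        n_flagged += int((~ok).sum())
        if not ok.any():
            continue
        cells = cells[ok]
        S = S[ok]
        vals_db = (
            10.0 * np.log10(S / Rp[None, :])
            + bsc_ref[bm][None, :]
            + (comp_rate[bm] * depths[r] * 100.0)[None, :]
        )
        f_mhz = freqs[bm] / 1e6
        A = np.stack([f_mhz, np.ones_like(f_mhz)], axis=1)
        coef, *_ = np.linalg.lstsq(A, vals_db.T, rcond=None)
        f_mid = 0.5 * (usable[0] + usable[1]) / 1e6
        maps["SS"][r, cells] = coef[0]
        maps["SI"][r, cells] = coef[1]
        maps["MBF"][r, cells] = coef[1] + coef[0] * f_mid
        asd, aac = _fit_sgm_batch(vals_db, freqs[bm], frame.transducer.sound_speed)
        maps["ASD"][r, cells] = asd
        maps["AAC"][r, cells] = aac

    if n_flagged > 0.5 * grid.n_inside:
        warnings.warn(
            f"quality failure: {n_flagged}/{grid.n_inside} windows flagged", stacklevel=2
        )
    out = {
        p: ParametricMap(parameter=p, values=maps[p], grid=grid, units=_MAP_UNITS[p])
        for p in MAP_PARAMETERS
    }
    return out, att
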