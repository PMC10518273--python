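"""Spectral preprocessing: detector merge, trimming, Savitzky-Golay
smoothing and localized standard normal variate (LSNV) normalization.

The default chain reproduces a common chemometric workflow for diffuse
reflectance spectra of cartilage: the two detector grids are merged at a
cutover wavelength inside their overlap, each spectrum is trimmed to
400-1400 nm and 1520-1850 nm (excising the saturated first-overtone OH
water band at 1400-1520 nm and the noisy long-wavelength tail), then
smoothed with a Savitzky-Golay filter and normalized by LSNV, i.e. SNV
applied within contiguous wavelength windows to remove local
multiplicative scatter effects.

Filtering and normalization are applied independently within each
contiguous segment of the trimmed grid, so no filter window ever mixes
values across the excised water band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .records import SpectrumRecord

logger = logging.getLogger(__name__)

#: Wavelength gap (nm) above which a trimmed grid is considered to break
#: into separate segments.  Large enough to ignore the Vis/NIR sampling
#: step change, small enough to catch the excised 1400-1520 nm band.
SEGMENT_GAP_NM = 50.0

DEFAULT_TRIM_WINDOWS = ((400.0, 1400.0), (1520.0, 1850.0))


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``steps`` lists the enabled operations in application order; trim
    runs first by default so that the excised bands define the segments
    within which smoothing and normalization operate.
    """

    trim_windows: tuple = DEFAULT_TRIM_WINDOWS
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_derivative: int = 0
    lsnv_window_nm: float = 200.0
    steps: tuple[str, ...] = ("trim", "savgol", "lsnv")

    def validate(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("polyorder must be smaller than the window")
        if self.lsnv_window_nm <= 0:
            raise ValueError("LSNV window width must be positive")
        wins = [tuple(w) for w in self.trim_windows]
        for (lo, hi) in wins:
            if lo > hi:
                raise ValueError("trim window bounds must be increasing")
        for (a, b), (c, d) in zip(wins, wins[1:]):
            if c <= b:
                raise ValueError("trim windows must be non-overlapping and increasing")
        for s in self.steps:
            if s not in ("trim", "savgol", "lsnv"):
                raise ValueError(f"unknown preprocessing step {s!r}")


def segment_slices(wavelengths: np.ndarray,
                   gap_nm: float = SEGMENT_GAP_NM) -> list[slice]:
    """Contiguous segments of a (possibly trimmed) wavelength grid."""
    if wavelengths.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(wavelengths) > gap_nm)
    edges = [0, *(breaks + 1), wavelengths.size]
    return [slice(a, b) for a, b in zip(edges, edges[1:])]


def merge_detectors(vis: SpectrumRecord, nir: SpectrumRecord,
                    cutover_nm: float = 1050.0) -> SpectrumRecord:
    """Merge the Vis and NIR detector records onto one increasing grid.

    Keeps the (finer) Vis samples up to and including the cutover
    wavelength and the NIR samples strictly above it.  Values are copied
    verbatim -- a step discontinuity between detectors is preserved.
    """
    if vis.wavelengths[-1] < nir.wavelengths[0]:
        raise ValueError("detector grids do not overlap")
    if not (vis.wavelengths[0] <= cutover_nm <= vis.wavelengths[-1]
            and nir.wavelengths[0] <= cutover_nm):
        raise ValueError("cutover wavelength must lie in the detector overlap")
    for key in ("donor_id", "site", "sample_id", "replicate", "oarsi_grade"):
        if getattr(vis, key) != getattr(nir, key):
            raise ValueError(f"detector records disagree on metadata field {key!r}")
    keep_vis = vis.wavelengths <= cutover_nm
    keep_nir = nir.wavelengths > cutover_nm
    wl = np.concatenate([vis.wavelengths[keep_vis], nir.wavelengths[keep_nir]])
    iy = np.concatenate([vis.intensities[keep_vis], nir.intensities[keep_nir]])
    return vis.with_data(wl, iy)


def trim_spectrum(s: SpectrumRecord,
                  windows=DEFAULT_TRIM_WINDOWS) -> SpectrumRecord:
    """Keep only wavelengths inside the closed trim windows."""
    mask = np.zeros(s.wavelengths.size, dtype=bool)
    for lo, hi in windows:
        mask |= (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError("trimming removed every wavelength")
    return s.with_data(s.wavelengths[mask], s.intensities[mask])


def savgol_smooth(s: SpectrumRecord, window: int = 11, polyorder: int = 2,
                  derivative: int = 0) -> SpectrumRecord:
    """Savitzky-Golay smoothing, applied per contiguous segment."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    y = s.intensities.copy()
    for seg in segment_slices(s.wavelengths):
        n = y[seg].size
        if n < window:
            raise ValueError(f"segment of {n} points shorter than SG window {window}")
        y[seg] = savgol_filter(y[seg], window, polyorder, deriv=derivative)
    return s.with_data(intensities=y)


def lsnv_normalize(s: SpectrumRecord, window_nm: float = 200.0) -> SpectrumRecord:
    """Localized SNV: z-score within contiguous wavelength windows.

    Each segment is partitioned into windows of ``window_nm`` starting
    at the segment's first wavelength (the last window may be shorter);
    windows never span the gap between segments.  A window with zero
    spread is an error.
    """
    if window_nm <= 0:
        raise ValueError("window width must be positive")
    y = s.intensities.copy()
    wl = s.wavelengths
    for seg in segment_slices(wl):
        seg_wl = wl[seg]
        start = seg_wl[0]
        n_win = int(np.ceil((seg_wl[-1] - start) / window_nm)) or 1
        idx = np.minimum(((seg_wl - start) / window_nm).astype(int), n_win - 1)
        sub = y[seg]
        for wi in np.unique(idx):
            m = idx == wi
            sd = sub[m].std()
            if sd == 0:
                raise ValueError("zero standard deviation within an LSNV window")
            sub[m] = (sub[m] - sub[m].mean()) / sd
        y[seg] = sub
    return s.with_data(intensities=y)


def preprocess_pipeline(records: list[SpectrumRecord],
                        cfg: PreprocessConfig | None = None
                        ) -> list[SpectrumRecord]:
    """Apply the configured chain to every record, preserving order and
    metadata; emits one log line per applied step."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = list(records)
    for step in cfg.steps:
        if step == "trim":
            logger.info("trim: windows=%s", cfg.trim_windows)
            out = [trim_spectrum(r, cfg.trim_windows) for r in out]
        elif step == "savgol":
            logger.info("savgol: window=%d polyorder=%d deriv=%d",
                        cfg.sg_window, cfg.sg_polyorder, cfg.sg_derivative)
            out = [savgol_smooth(r, cfg.sg_window, cfg.sg_polyorder,
                                 cfg.sg_derivative) for r in out]
        elif step == "lsnv":
            logger.info("lsnv: window_nm=%s", cfg.lsnv_window_nm)
            out = [lsnv_normalize(r, cfg.lsnv_window_nm) for r in out]
    if len(out) != len(records):
        raise RuntimeError("preprocessing must not drop or duplicate records")
    return out
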