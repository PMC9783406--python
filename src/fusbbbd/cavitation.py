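"""Cavitation-dose metrics from passive cavitation detector (PCD) recordings.

During microbubble-mediated blood-brain-barrier opening, a passive detector
records acoustic emissions for every sonication burst.  Stable bubble
oscillation radiates energy at harmonics of the driving frequency (n * fc)
and at sub/ultra-harmonics (n * fc / 2, odd n); inertial collapse radiates
broadband noise.  This module segments a recording into bursts, computes a
Parseval-scaled amplitude spectrum per burst, reads out harmonic,
ultraharmonic and broadband band levels, normalizes them to a
no-microbubble baseline recording, and integrates the baseline excess over
the sonication to yield three cumulative dose metrics:

* ``scd_h`` -- stable cavitation dose from harmonic emission,
* ``scd_u`` -- stable cavitation dose from sub/ultra-harmonic emission,
* ``icd``  -- inertial cavitation dose from broadband emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PCDRecording",
    "BandConfig",
    "BurstBandPowers",
    "CavitationDoses",
    "segment_bursts",
    "burst_spectrum",
    "band_powers",
    "baseline_normalize",
    "cavitation_doses",
    "compute_doses",
]

BANDS = ("harmonic", "ultraharmonic", "broadband")


@dataclass
class PCDRecording:
    """Burst-segmented voltage trace from a passive cavitation detector.

    ``samples`` is either a flat 1-D trace (bursts located via
    ``burst_onsets``) or a 2-D array of shape (n_bursts, window_length)
    holding the burst windows themselves, one row per entry of
    ``burst_onsets``.
    """

    samples: np.ndarray
    sampling_rate: float          # Hz
    burst_onsets: np.ndarray      # s, strictly increasing
    burst_length: float           # s
    fundamental_fc: float         # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.burst_onsets = np.asarray(self.burst_onsets, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.burst_length <= 0:
            raise ValueError("burst_length must be positive")
        if self.burst_onsets.ndim != 1 or self.burst_onsets.size == 0:
            raise ValueError("burst_onsets must be a nonempty 1-D array")
        if np.any(np.diff(self.burst_onsets) <= 0):
            raise ValueError("burst_onsets must be strictly increasing")
        if self.samples.ndim == 2 and self.samples.shape[0] != self.burst_onsets.size:
            raise ValueError("stacked samples must have one row per burst onset")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or 2-D")

    @property
    def window_samples(self) -> int:
        return int(round(self.burst_length * self.sampling_rate))

    @property
    def n_bursts(self) -> int:
        return int(self.burst_onsets.size)


@dataclass
class BandConfig:
    """Spectral band layout for dose readout.

    Harmonic centers sit at n*fc, ultraharmonic centers at n*fc/2 for odd n
    (n = 1 is the subharmonic; the dose metric pools sub- and
    ultra-harmonics).  The broadband readout covers ``analysis_band`` after
    carving out ``broadband_exclusion_halfwidth`` around every tonal center.
    """

    harmonic_orders: tuple = (1, 2, 3, 4)
    ultraharmonic_orders: tuple = (1, 3, 5, 7)
    band_halfwidth: float = 50e3               # Hz
    broadband_exclusion_halfwidth: float = 150e3   # Hz
    analysis_band: tuple = (0.3e6, 5.0e6)      # Hz, detector passband

    def __post_init__(self) -> None:
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")
        if self.broadband_exclusion_halfwidth <= 0:
            raise ValueError("broadband_exclusion_halfwidth must be positive")
        if any(n % 2 == 0 for n in self.ultraharmonic_orders):
            raise ValueError("ultraharmonic orders must be odd (centers at n*fc/2)")
        if self.analysis_band[0] >= self.analysis_band[1]:
            raise ValueError("analysis_band must be (f_lo, f_hi) with f_lo < f_hi")

    def tonal_centers(self, fc: float) -> tuple[np.ndarray, np.ndarray]:
        """(harmonic centers, ultraharmonic centers) in Hz for fundamental fc."""
        harm = fc * np.asarray(self.harmonic_orders, dtype=float)
        ultra = 0.5 * fc * np.asarray(self.ultraharmonic_orders, dtype=float)
        return harm, ultra

    def validate_against(self, fc: float, nyquist: float) -> None:
        harm, ultra = self.tonal_centers(fc)
        centers = np.sort(np.concatenate([harm, ultra]))
        if np.any(np.diff(centers) < 2 * self.band_halfwidth):
            raise ValueError("harmonic and ultraharmonic bands overlap")
        if self.analysis_band[1] > nyquist:
            raise ValueError("analysis_band exceeds the Nyquist frequency")


@dataclass
class BurstBandPowers:
    """Per-burst band readout (RMS amplitude units of the input trace)."""

    burst_time: float       # s
    harmonic_rms: float
    ultraharmonic_rms: float
    broadband_rms: float


@dataclass
class CavitationDoses:
    """Cumulative doses (dimensionless baseline-excess integrated over s)."""

    scd_h: float
    scd_u: float
    icd: float

    def as_dict(self) -> dict:
        return {"scd_h": self.scd_h, "scd_u": self.scd_u, "icd": self.icd}


def segment_bursts(rec: PCDRecording) -> list[np.ndarray]:
    """Extract one fixed-length sample window per burst, in time order."""
    n = rec.window_samples
    if rec.samples.ndim == 2:
        if rec.samples.shape[1] != n:
            raise ValueError(
                f"stacked window length {rec.samples.shape[1]} != "
                f"round(burst_length * sampling_rate) = {n}"
            )
        return [rec.samples[i] for i in range(rec.n_bursts)]
    windows = []
    for onset in rec.burst_onsets:
        start = int(round(onset * rec.sampling_rate))
        stop = start + n
        if start < 0 or stop > rec.samples.size:
            raise ValueError(f"burst at t={onset:g}s extends past the end of the trace")
        windows.append(rec.samples[start:stop])
    return windows


def burst_spectrum(
    window: np.ndarray, sampling_rate: float, taper: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a burst window.

    Scaling is Parseval-consistent: with a rectangular taper the sum of
    squared spectral amplitudes equals the mean squared signal exactly; a
    tapered spectrum is normalized by the taper's RMS so that broadband
    power is preserved in expectation (tonal peak amplitudes then carry the
    usual coherent-gain/noise-gain bias, which cancels in baseline
    normalization).

    Returns (freqs [Hz], amplitudes [RMS units]).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D array with at least 2 samples")
    n = window.size
    if taper == "hann":
        w = np.hanning(n)
    elif taper in ("rect", "rectangular", "boxcar"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    # normalize so that sum(amp^2) estimates mean(x^2) (Parseval)
    scale = 1.0 / (n * np.sqrt(np.mean(w**2)))
    spec = np.fft.rfft(window * w)
    amp = np.abs(spec) * scale
    # one-sided doubling of interior bins (power folds from negative freqs)
    amp[1:] *= np.sqrt(2.0)
    if n % 2 == 0:
        amp[-1] /= np.sqrt(2.0)  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return freqs, amp


def _band_mask(freqs: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    return np.abs(freqs - center) <= halfwidth


def band_powers(
    freqs: np.ndarray,
    amplitudes: np.ndarray,
    fc: float,
    band_cfg: BandConfig | None = None,
    burst_time: float = 0.0,
) -> BurstBandPowers:
    """Read harmonic / ultraharmonic / broadband levels off one spectrum.

    Harmonic RMS is the root-sum-square over orders of the peak amplitude
    within +/- band_halfwidth of each n*fc center (the "peak value around
    each harmonic"); ultraharmonic likewise at n*fc/2 for odd n.  Broadband
    RMS is the root-sum-square of all bins in the analysis band after
    excluding +/- broadband_exclusion_halfwidth around every tonal center.
    """
    cfg = band_cfg or BandConfig()
    freqs = np.asarray(freqs, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    cfg.validate_against(fc, nyquist=freqs[-1])
    harm_centers, ultra_centers = cfg.tonal_centers(fc)

    def peak_rss(centers: np.ndarray) -> float:
        total = 0.0
        for c in centers:
            m = _band_mask(freqs, c, cfg.band_halfwidth)
            if not m.any():
                raise ValueError(f"band at {c:g} Hz lies outside the spectrum")
            total += float(np.max(amplitudes[m]) ** 2)
        return np.sqrt(total)

    bb = (freqs >= cfg.analysis_band[0]) & (freqs <= cfg.analysis_band[1])
    for c in np.concatenate([harm_centers, ultra_centers]):
        bb &= ~_band_mask(freqs, c, cfg.broadband_exclusion_halfwidth)
    broadband = float(np.sqrt(np.sum(amplitudes[bb] ** 2)))

    return BurstBandPowers(
        burst_time=burst_time,
        harmonic_rms=peak_rss(harm_centers),
        ultraharmonic_rms=peak_rss(ultra_centers),
        broadband_rms=broadband,
    )


def recording_band_powers(
    rec: PCDRecording, band_cfg: BandConfig | None = None, taper: str = "hann"
) -> pd.DataFrame:
    """Band powers for every burst of a recording.

    Returns a DataFrame with columns burst_time_s, harmonic, ultraharmonic,
    broadband (one row per burst).
    """
    rows = []
    for onset, window in zip(rec.burst_onsets, segment_bursts(rec)):
        freqs, amp = burst_spectrum(window, rec.sampling_rate, taper=taper)
        bp = band_powers(freqs, amp, rec.fundamental_fc, band_cfg, burst_time=onset)
        rows.append(
            {
                "burst_time_s": bp.burst_time,
                "harmonic": bp.harmonic_rms,
                "ultraharmonic": bp.ultraharmonic_rms,
                "broadband": bp.broadband_rms,
            }
        )
    return pd.DataFrame(rows)


def baseline_normalize(
    treatment: pd.DataFrame, baseline: pd.DataFrame, floor: bool = True
) -> pd.DataFrame:
    """Normalize per-burst band levels to a no-microbubble baseline.

    Each band column is divided by the time-mean of the corresponding
    baseline column, yielding dimensionless ratios.  Ratios below 1 are
    floored at 1 (emission at or below baseline level contributes no excess
    dose); pass ``floor=False`` to keep raw ratios.
    """
    if len(treatment) == 0 or len(baseline) == 0:
        raise ValueError("treatment and baseline series must be nonempty")
    out = treatment.copy()
    for band in BANDS:
        mean = float(baseline[band].mean())
        if mean <= 0:
            raise ValueError(f"baseline mean of zero in band {band!r}")
        out[band] = treatment[band] / mean
        if floor:
            out[band] = out[band].clip(lower=1.0)
    return out


def cavitation_doses(
    normalized: pd.DataFrame, integrand: str = "rms_excess"
) -> CavitationDoses:
    """Integrate baseline-excess band levels over the sonication.

    Per band, dose = trapezoidal integral over burst time of
    (normalized value - 1); with ``integrand='power_excess'`` the ratio is
    squared before subtracting 1 (power rather than RMS units).
    """
    if len(normalized) < 2:
        raise ValueError("need at least 2 bursts to integrate a dose")
    if integrand not in ("rms_excess", "power_excess"):
        raise ValueError(f"unknown integrand {integrand!r}")
    t = normalized["burst_time_s"].to_numpy(dtype=float)
    doses = {}
    for band in BANDS:
        r = normalized[band].to_numpy(dtype=float)
        excess = (r**2 - 1.0) if integrand == "power_excess" else (r - 1.0)
        doses[band] = float(np.trapezoid(np.clip(excess, 0.0, None), t))
    return CavitationDoses(
        scd_h=doses["harmonic"], scd_u=doses["ultraharmonic"], icd=doses["broadband"]
    )


def compute_doses(
    treatment: PCDRecording,
    baseline: PCDRecording,
    band_cfg: BandConfig | None = None,
    taper: str = "hann",
    integrand: str = "rms_excess",
) -> tuple[CavitationDoses, pd.DataFrame]:
    """Full pipeline: spectra -> band powers -> normalization -> doses.

    Returns (doses, normalized per-burst band table).
    """
    treat_bp = recording_band_powers(treatment, band_cfg, taper)
    base_bp = recording_band_powers(baseline, band_cfg, taper)
    norm = baseline_normalize(treat_bp, base_bp)
    return cavitation_doses(norm, integrand=integrand), norm
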