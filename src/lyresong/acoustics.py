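"""Spectrograms and per-element acoustic measurements.

Measurements follow the robust, energy-based definitions used by sound
analysis software for selection boxes on a spectrogram: the 90% duration
and 90% bandwidth are the spans between the 5% and 95% cumulative-energy
quantiles (computed on linear power, not dB), the peak frequency is the
bin with the highest power anywhere in the box, the centre frequency
splits the box energy into two equal halves by frequency, and the peak
frequency contour is the per-frame argmax frequency. First/last frequency
and element slope (last minus first) derive from the contour.

Conventions: Hann window, FFT length 1024 by default, 50% overlap, frame
times at frame centres, bin frequencies at bin centres, selection boxes
closed on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class Spectrogram:
    """Magnitude-squared STFT with explicit axes.

    ``power[k, t]`` is the squared magnitude of the raw (un-normalised)
    one-sided DFT of the Hann-windowed frame, so summing over a column and
    doubling the interior bins recovers ``n_fft x`` the windowed frame
    energy (Parseval).
    """

    power: np.ndarray      # (freq_bins, frames), linear power
    freq_axis: np.ndarray  # Hz, bin centres
    time_axis: np.ndarray  # s, frame centres
    window: str
    n_fft: int
    hop: int

    @property
    def hop_s(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0]) if len(self.time_axis) > 1 \
            else self.hop / 1.0

    @property
    def bin_hz(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0])


@dataclass
class ElementSelection:
    """A time x frequency selection box on the spectrogram."""

    begin_s: float
    end_s: float
    low_Hz: float
    high_Hz: float
    song_id: str = ""
    element_index: int = 0

    def __post_init__(self):
        if not self.begin_s < self.end_s:
            raise ValueError("selection must have begin < end")
        if not self.low_Hz < self.high_Hz:
            raise ValueError("selection must have low < high frequency")


@dataclass
class ElementMeasures:
    begin_s: float
    end_s: float
    duration90_s: float
    peak_freq_Hz: float
    center_freq_Hz: float
    bandwidth90_Hz: float
    freq5_Hz: float
    freq95_Hz: float
    contour: np.ndarray
    first_freq_Hz: float
    last_freq_Hz: float
    slope_Hz: float


def spectrogram(waveform, sample_rate, n_fft: int = 1024, window: str = "hann",
                overlap_fraction: float = 0.5) -> Spectrogram:
    """Short-time power spectrogram of a 1-D waveform."""
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if n_fft <= 0:
        raise ValueError("n_fft must be positive")
    if n_fft > x.size:
        raise ValueError("n_fft longer than waveform")
    noverlap = int(round(n_fft * overlap_fraction))
    hop = n_fft - noverlap
    win = sps.get_window(window, n_fft)
    freqs, times, Z = sps.stft(x, fs=sample_rate, window=win, nperseg=n_fft,
                               noverlap=noverlap, boundary=None, padded=False,
                               return_onesided=True)
    # undo scipy's 1/sum(win) scaling: power = |raw windowed DFT|^2
    Z = Z * win.sum()
    return Spectrogram(power=np.abs(Z) ** 2, freq_axis=freqs, time_axis=times,
                       window=window, n_fft=n_fft, hop=hop)


def _quantile_crossing(axis: np.ndarray, marginal: np.ndarray, q: float) -> float:
    """Axis value where cumulative energy reaches fraction ``q``.

    Linearly interpolated between frame/bin centres; clamped to the axis.
    """
    cum = np.cumsum(marginal)
    return float(np.interp(q * cum[-1], cum, axis))


def measure_element(spec: Spectrogram, sel: ElementSelection,
                    contour_floor: float = 1e-6) -> ElementMeasures:
    """Energy-based measurements of one selection box.

    ``contour_floor`` excludes contour frames whose in-box power is below
    ``contour_floor x`` the maximum frame power, so silent frames at the
    edges of a box cannot supply contour endpoints.
    """
    tmask = (spec.time_axis >= sel.begin_s) & (spec.time_axis <= sel.end_s)
    fmask = (spec.freq_axis >= sel.low_Hz) & (spec.freq_axis <= sel.high_Hz)
    if tmask.sum() < 1 or fmask.sum() < 2:
        raise ValueError("selection overlaps fewer than 1 frame / 2 frequency bins")
    P = spec.power[np.ix_(fmask, tmask)]
    if P.sum() <= 0:
        raise ValueError("zero energy inside selection")
    t_ax = spec.time_axis[tmask]
    f_ax = spec.freq_axis[fmask]

    t_marg = P.sum(axis=0)
    f_marg = P.sum(axis=1)
    t05 = _quantile_crossing(t_ax, t_marg, 0.05)
    t95 = _quantile_crossing(t_ax, t_marg, 0.95)
    f05 = _quantile_crossing(f_ax, f_marg, 0.05)
    f95 = _quantile_crossing(f_ax, f_marg, 0.95)
    center = _quantile_crossing(f_ax, f_marg, 0.50)

    kf, kt = np.unravel_index(int(np.argmax(P)), P.shape)
    peak = float(f_ax[kf])

    frame_pow = t_marg
    keep = frame_pow >= contour_floor * frame_pow.max()
    contour = f_ax[np.argmax(P[:, keep], axis=0)] if keep.any() else np.array([peak])
    first = float(contour[0])
    last = float(contour[-1])

    return ElementMeasures(
        begin_s=sel.begin_s, end_s=sel.end_s,
        duration90_s=t95 - t05,
        peak_freq_Hz=peak, center_freq_Hz=center,
        bandwidth90_Hz=f95 - f05, freq5_Hz=f05, freq95_Hz=f95,
        contour=np.asarray(contour, dtype=float),
        first_freq_Hz=first, last_freq_Hz=last, slope_Hz=last - first,
    )


MEASURE_COLUMNS = [
    "begin_s", "end_s", "duration90_s", "peak_freq_Hz", "center_freq_Hz",
    "bandwidth90_Hz", "freq5_Hz", "freq95_Hz", "first_freq_Hz",
    "last_freq_Hz", "slope_Hz",
]


def measure_table(waveform, sample_rate, selections, n_fft: int = 1024,
                  overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Measure every selection of one recording; one row per selection.

    Selections must be sorted by begin time; overlapping boxes only warn.
    Rows carry ``song_id`` and ``element_index`` through.
    """
    import warnings

    sels = list(selections)
    if not sels:
        return pd.DataFrame(columns=["song_id", "element_index", *MEASURE_COLUMNS])
    begins = [s.begin_s for s in sels]
    if begins != sorted(begins):
        raise ValueError("selections must be sorted by begin time")
    for a, b in zip(sels[:-1], sels[1:]):
        if a.song_id == b.song_id and b.begin_s < a.end_s:
            warnings.warn(f"overlapping selections in song {a.song_id!r}")
    spec = spectrogram(waveform, sample_rate, n_fft=n_fft,
                       overlap_fraction=overlap_fraction)
    rows = []
    for s in sels:
        m = measure_element(spec, s)
        row = {"song_id": s.song_id, "element_index": s.element_index}
        row.update({c: getattr(m, c) for c in MEASURE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)
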