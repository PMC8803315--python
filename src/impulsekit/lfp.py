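"""Task-period LFP power spectra and event-locked spectrogram statistics.

Power is estimated with short-time modified periodograms (Welch segments of
1 s, 50% overlap, Hann taper) restricted to the 3-200 Hz passband.  Around
task events the averaged time-frequency power is normalized within each
frequency row by that row's own mean and SD over the peri-event window
("within-frequency Z-scoring"), then averaged within theta/beta/gamma bands
and 2 s time bins.  Raw (non-normalized) band power in the single 2 s bin
preceding the event, and the variance of raw band power across all bins of
the peri-event range, feed channel-paired Wilcoxon signed-rank comparisons
between conditions (e.g. vehicle vs treatment).

Band edges are configurable; defaults are conventional rodent definitions
(theta 4-12, beta 15-30, gamma 30-90 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "LFPRecord",
    "BandSet",
    "SpectrogramZ",
    "BandTimecourse",
    "period_psd",
    "event_spectrogram_z",
    "band_timecourse",
    "pre_event_power_stats",
    "DEFAULT_BANDS",
]

PASSBAND = (3.0, 200.0)


@dataclass(frozen=True)
class LFPRecord:
    """One LFP channel: regularly sampled voltage within the 3-200 Hz band."""

    channel_id: str
    samples: np.ndarray
    fs_hz: float
    passband: tuple[float, float] = PASSBAND

    def __post_init__(self) -> None:
        if self.fs_hz < 2 * self.passband[1]:
            raise ValueError("sampling rate below 2x the passband top")
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass(frozen=True)
class BandSet:
    """Named frequency bands (Hz)."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r}: need 0 < low < high")

    def items(self):
        return self.bands.items()


DEFAULT_BANDS = BandSet({"theta": (4.0, 12.0), "beta": (15.0, 30.0),
                         "gamma": (30.0, 90.0)})


@dataclass(frozen=True)
class SpectrogramZ:
    """Event-averaged, within-frequency Z-scored spectrogram.

    ``z[f, t]`` has row-wise mean ~0 and SD ~1 over the peri-event window;
    ``power`` keeps the raw event-averaged power for non-normalized
    statistics.
    """

    frequencies: np.ndarray
    times: np.ndarray           # bin centers relative to the event, s
    z: np.ndarray               # (n_freq, n_time)
    power: np.ndarray           # raw event-averaged power, same shape
    n_events: int
    n_dropped_events: int = 0


@dataclass(frozen=True)
class BandTimecourse:
    band_names: tuple[str, ...]
    bin_centers: np.ndarray     # relative to event, s
    values: np.ndarray          # (n_bands, n_bins)
    bin_s: float
    baseline_bin: int = 0


# ---------------------------------------------------------------------------

def period_psd(lfp: LFPRecord, intervals: Sequence[tuple[float, float]],
               segment_s: float = 1.0, overlap: float = 0.5):
    """Averaged Welch spectrum over a set of task-period intervals.

    Segments of ``segment_s`` with the given fractional overlap and a Hann
    taper; interval spectra are combined weighted by interval duration and
    restricted to the 3-200 Hz passband.  Returns ``(freqs, psd)``.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    fs = lfp.fs_hz
    nper = int(round(segment_s * fs))
    acc = None
    freqs = None
    total = 0.0
    for a, b in intervals:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        if i0 < 0 or i1 > len(lfp.samples) or i1 <= i0:
            raise ValueError(f"interval ({a}, {b}) outside the record")
        seg = lfp.samples[i0:i1]
        nseg = min(nper, len(seg))
        f, p = signal.welch(seg, fs=fs, nperseg=nseg,
                            noverlap=int(round(nseg * overlap)))
        if freqs is None:
            freqs, acc = f, p * (b - a)
        else:
            if len(f) != len(freqs):      # shorter interval: re-estimate on grid
                f, p = signal.welch(seg, fs=fs, nperseg=nper,
                                    noverlap=int(round(nper * overlap)))
            acc = acc + p * (b - a)
        total += b - a
    psd = acc / total
    sel = (freqs >= lfp.passband[0]) & (freqs <= lfp.passband[1])
    return freqs[sel], psd[sel]


def _stft_power(lfp: LFPRecord, segment_s: float, overlap: float):
    fs = lfp.fs_hz
    nper = int(round(segment_s * fs))
    step = nper - int(round(nper * overlap))
    f, t, sxx = signal.spectrogram(lfp.samples, fs=fs, nperseg=nper,
                                   noverlap=nper - step, window="hann",
                                   scaling="density", mode="psd")
    sel = (f >= lfp.passband[0]) & (f <= lfp.passband[1])
    return f[sel], t, sxx[sel]


def event_spectrogram_z(lfp: LFPRecord, event_times,
                        window: tuple[float, float] = (-8.0, 8.0),
                        segment_s: float = 1.0,
                        overlap: float = 0.5) -> SpectrogramZ:
    """Event-averaged spectrogram, Z-scored within each frequency row.

    The short-time power of the whole record is computed once, event
    windows are cut on the spectrogram's time grid and averaged, and each
    frequency row is normalized by its own mean/SD over the window.  Events
    whose window exceeds the record are dropped and counted.
    """
    event_times = np.asarray(event_times, dtype=float)
    f, t, sxx = _stft_power(lfp, segment_s, overlap)
    hop = t[1] - t[0] if len(t) > 1 else segment_s
    n_pre = int(round(-window[0] / hop))
    n_post = int(round(window[1] / hop))
    anchors = np.round((event_times - t[0]) / hop).astype(int)
    ok = (anchors - n_pre >= 0) & (anchors + n_post <= len(t))
    dropped = int(np.sum(~ok))
    anchors = anchors[ok]
    if len(anchors) < 2:
        raise ValueError(f"fewer than 2 events retained ({dropped} dropped)")
    offs = np.arange(-n_pre, n_post)
    cut = sxx[:, anchors[:, None] + offs[None, :]]     # (f, ev, time)
    power = cut.mean(axis=1)
    mu = power.mean(axis=1, keepdims=True)
    sd = power.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (power - mu) / sd
    rel_times = (offs + 0.5) * hop
    return SpectrogramZ(frequencies=f, times=rel_times, z=z, power=power,
                        n_events=len(anchors), n_dropped_events=dropped)


def _band_rows(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    rows = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if len(rows) == 0:
        raise ValueError(f"band {band} contains no frequency rows")
    return rows


def band_timecourse(spec: SpectrogramZ, bands: BandSet = DEFAULT_BANDS,
                    bin_s: float = 2.0, use_z: bool = True) -> BandTimecourse:
    """Band-averaged, fixed-width-binned time course of a spectrogram.

    Averages the (Z-scored by default) spectrogram across each band's
    frequency rows, then within consecutive ``bin_s`` time bins; the number
    of output bins is ``floor(window / bin_s)``.  The baseline bin is the
    earliest (most pre-event) bin.
    """
    mat = spec.z if use_z else spec.power
    hop = spec.times[1] - spec.times[0]
    per_bin = max(int(round(bin_s / hop)), 1)
    n_bins = mat.shape[1] // per_bin
    names = tuple(bands.bands)
    rows_by_band = [_band_rows(spec.frequencies, bands.bands[n]) for n in names]
    out = np.empty((len(names), n_bins))
    centers = np.empty(n_bins)
    for j in range(n_bins):
        sl = slice(j * per_bin, (j + 1) * per_bin)
        centers[j] = spec.times[sl].mean()
        for i, rows in enumerate(rows_by_band):
            out[i, j] = mat[rows, sl].mean()
    return BandTimecourse(band_names=names, bin_centers=centers, values=out,
                          bin_s=bin_s, baseline_bin=0)


# ---------------------------------------------------------------------------

def pre_event_power_stats(lfp_by_condition: Mapping[str, Sequence[LFPRecord]],
                          events_by_condition: Mapping[str, Sequence[float]],
                          bands: BandSet = DEFAULT_BANDS,
                          window: tuple[float, float] = (-8.0, 8.0),
                          bin_s: float = 2.0, segment_s: float = 1.0,
                          overlap: float = 0.5):
    """Channel-paired pre-event band power and band-power variance.

    For each condition and channel the raw event-averaged spectrogram is
    band-averaged into 2 s bins; the pre-event statistic is the power of
    the single bin immediately preceding the event (covering [-2, 0) s) and
    the variance statistic is the variance of band power across all bins of
    the peri-event range.  The two conditions are compared per band with a
    two-sided Wilcoxon paired signed-rank test across channels.

    Returns ``(per_channel, tests)`` DataFrames.
    """
    conds = list(lfp_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    ids = [sorted(r.channel_id for r in lfp_by_condition[c]) for c in conds]
    if ids[0] != ids[1]:
        missing = sorted(set(ids[0]).symmetric_difference(ids[1]))
        raise ValueError(f"unpaired channels: {missing}")

    rows = []
    for cond in conds:
        events = events_by_condition[cond]
        for rec in lfp_by_condition[cond]:
            spec = event_spectrogram_z(rec, events, window=window,
                                       segment_s=segment_s, overlap=overlap)
            tc = band_timecourse(spec, bands, bin_s=bin_s, use_z=False)
            pre_bin = int(np.argmin(np.abs(tc.bin_centers - (-bin_s / 2))))
            for i, name in enumerate(tc.band_names):
                rows.append({
                    "condition": cond, "channel_id": rec.channel_id,
                    "band": name,
                    "pre_event_power": float(tc.values[i, pre_bin]),
                    "power_variance": float(np.var(tc.values[i], ddof=1)),
                })
    per_channel = pd.DataFrame(rows)

    tests = []
    for name in bands.bands:
        sub = per_channel[per_channel["band"] == name]
        a = sub[sub["condition"] == conds[0]].sort_values("channel_id")
        b = sub[sub["condition"] == conds[1]].sort_values("channel_id")
        for measure in ("pre_event_power", "power_variance"):
            x = a[measure].to_numpy()
            y = b[measure].to_numpy()
            d = x - y
            if np.allclose(d, 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(x, y, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            tests.append({"band": name, "measure": measure,
                          "statistic": stat, "p_value": p,
                          "median_diff": float(np.median(d)),
                          "n_pairs": len(d)})
    return per_channel, pd.DataFrame(tests)
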