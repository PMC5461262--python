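"""Measurement channels: spike counting and the simulated LFP.

Two chains process the raw 20 kHz model output after a 1 s settle discard:

* AP channel — resample to 5 kHz, 9th-order Butterworth high-pass at
  50 Hz (zero-phase), threshold-crossing count with a 2 ms lockout.
* LFP channel — distance-weighted sum of all compartment membrane
  potentials at a virtual electrode above the patch centre, resampled to
  1 kHz and low-pass filtered with an 8th-order Butterworth at 300 Hz
  (zero-phase).

The LFP forward model is the monopole-style 1/r sum (1/r² available via
configuration); its output is in model units (V/µm), not calibrated
volts.  Filtering is applied forward–backward so band-power comparisons
are not phase-distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ElectrodeSpec", "TimeSeries", "SpikeRecord", "lfp_weights", "lfp_sample",
    "settle_trim", "ap_signal_chain", "lfp_signal_chain", "detect_aps",
    "mean_firing_rate", "save_timeseries_h5", "load_timeseries_h5",
]

RAW_RATE_HZ = 20_000.0
AP_RATE_HZ = 5_000.0
LFP_RATE_HZ = 1_000.0
AP_HP_ORDER, AP_HP_CUTOFF_HZ = 9, 50.0
LFP_LP_ORDER, LFP_LP_CUTOFF_HZ = 8, 300.0
AGGREGATE_AP_THRESHOLD = 2.5e-8      # model units, aggregate channel
SOMATIC_AP_THRESHOLD_V = 0.02        # volts, per-neuron somatic channel
AP_LOCKOUT_S = 2e-3


@dataclass(frozen=True)
class ElectrodeSpec:
    """Virtual electrode above the patch centre.

    ``z_um`` is negative (above the pia; depth increases with +z).
    ``min_distance_clamp_um`` guards the 1/r weight against a compartment
    sitting arbitrarily close to the electrode.
    """

    x_um: float
    y_um: float
    z_um: float = -500.0
    min_distance_clamp_um: float = 10.0
    weighting: str = "1/r"           # or "1/r2"

    def __post_init__(self):
        if self.min_distance_clamp_um <= 0:
            raise ValueError("distance clamp must be positive")
        if self.weighting not in ("1/r", "1/r2"):
            raise ValueError("weighting must be '1/r' or '1/r2'")

    @classmethod
    def default_for(cls, config) -> "ElectrodeSpec":
        half = config.patch_xy_um / 2.0
        return cls(x_um=half, y_um=half)

    @property
    def position_um(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um])


@dataclass
class TimeSeries:
    """Uniformly sampled signal with its rate and start time."""

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.rate_hz


@dataclass
class SpikeRecord:
    """Per-neuron AP counts and the population mean rate."""

    per_neuron_counts: np.ndarray
    duration_s: float
    spike_times: Optional[pd.DataFrame] = None   # columns neuron_id, spike_time_ms

    @property
    def total_ap_count(self) -> int:
        return int(self.per_neuron_counts.sum())

    @property
    def mean_rate(self) -> float:
        return mean_firing_rate(self.total_ap_count, self.duration_s)

    def to_csv(self, path) -> None:
        if self.spike_times is not None:
            self.spike_times.to_csv(path, index=False)
        else:
            pd.DataFrame({
                "neuron_id": np.arange(len(self.per_neuron_counts)),
                "ap_count": self.per_neuron_counts,
            }).to_csv(path, index=False)


def lfp_weights(comp_pos_um: np.ndarray, electrode: ElectrodeSpec) -> np.ndarray:
    """Per-compartment weights 1/max(r, clamp) (or 1/r²) in µm⁻¹ (µm⁻²)."""
    r = np.linalg.norm(np.asarray(comp_pos_um, dtype=float)
                       - electrode.position_um, axis=1)
    r = np.maximum(r, electrode.min_distance_clamp_um)
    return 1.0 / r if electrode.weighting == "1/r" else 1.0 / r**2


def lfp_sample(comp_voltages: np.ndarray, comp_pos_um: np.ndarray,
               electrode: ElectrodeSpec) -> float:
    """Σ_k V_k / max(r_k, clamp): one LFP sample at the electrode."""
    return float(lfp_weights(comp_pos_um, electrode) @ np.asarray(comp_voltages))


def settle_trim(series: TimeSeries, settle_s: float = 1.0) -> TimeSeries:
    """Drop the initial settle window (model relaxing from initial state)."""
    if settle_s < 0:
        raise ValueError("settle must be nonnegative")
    if settle_s == 0:
        return TimeSeries(series.samples.copy(), series.rate_hz, series.t0_s)
    n = int(round(settle_s * series.rate_hz))
    if n >= len(series.samples):
        raise ValueError("series shorter than the settle window")
    return TimeSeries(series.samples[n:].copy(), series.rate_hz,
                      series.t0_s + settle_s)


def _aa_filter(up: int, down: int) -> np.ndarray:
    """Sharp anti-alias FIR for polyphase resampling (flat to ~0.8·Nyquist)."""
    m = max(up, down)
    taps = 64 * m + 1
    h = signal.firwin(taps, 0.92 / m, window=("kaiser", 9.0))
    return h * up


def _resample(series_or_array, out_rate: float, in_rate: Optional[float] = None,
              axis: int = -1):
    if isinstance(series_or_array, TimeSeries):
        x, rate, t0 = series_or_array.samples, series_or_array.rate_hz, series_or_array.t0_s
    else:
        x, rate, t0 = np.asarray(series_or_array, dtype=float), in_rate, 0.0
    up = int(round(out_rate))
    down = int(round(rate))
    g = np.gcd(up, down)
    up, down = up // g, down // g
    y = signal.resample_poly(x, up, down, axis=axis, window=_aa_filter(up, down))
    if isinstance(series_or_array, TimeSeries):
        return TimeSeries(y, out_rate, t0)
    return y


def ap_signal_chain(raw: TimeSeries) -> TimeSeries:
    """20 kHz → 5 kHz anti-aliased resample → 9th-order 50 Hz high-pass."""
    if raw.rate_hz != RAW_RATE_HZ:
        raise ValueError(f"AP chain expects {RAW_RATE_HZ:.0f} Hz input")
    sos = signal.butter(AP_HP_ORDER, AP_HP_CUTOFF_HZ, "highpass",
                        fs=AP_RATE_HZ, output="sos")
    ts = _resample(raw, AP_RATE_HZ)
    y = signal.sosfiltfilt(sos, ts.samples)
    return TimeSeries(y, AP_RATE_HZ, raw.t0_s)


def lfp_signal_chain(raw: TimeSeries) -> TimeSeries:
    """20 kHz → 1 kHz anti-aliased resample → 8th-order 300 Hz low-pass."""
    if raw.rate_hz != RAW_RATE_HZ:
        raise ValueError(f"LFP chain expects {RAW_RATE_HZ:.0f} Hz input")
    ts = _resample(raw, LFP_RATE_HZ)
    sos = signal.butter(LFP_LP_ORDER, LFP_LP_CUTOFF_HZ, "lowpass",
                        fs=LFP_RATE_HZ, output="sos")
    y = signal.sosfiltfilt(sos, ts.samples)
    return TimeSeries(y, LFP_RATE_HZ, raw.t0_s)


def detect_aps(sig: TimeSeries, threshold: float = AGGREGATE_AP_THRESHOLD,
               lockout_s: float = AP_LOCKOUT_S) -> tuple[int, np.ndarray]:
    """Count upward threshold crossings with a lockout window.

    Returns (count, crossing times in s).  Intended for the output of
    ``ap_signal_chain`` — either the aggregate signal at the default
    threshold or per-neuron somatic traces at a somatic threshold.
    """
    x = sig.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in spike-detection signal")
    above = x >= threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if len(crossings) == 0:
        return 0, np.empty(0)
    lockout = int(round(lockout_s * sig.rate_hz))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] > lockout:
            kept.append(c)
    times = sig.t0_s + np.asarray(kept) / sig.rate_hz
    return len(kept), times


def mean_firing_rate(total_count: int, duration_s: float) -> float:
    """Total APs across all neurons divided by the simulation length."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return total_count / duration_s


def count_aps_per_neuron(soma_traces: np.ndarray, rate_hz: float, t0_s: float = 0.0,
                         threshold: float = SOMATIC_AP_THRESHOLD_V) -> np.ndarray:
    """Run the AP chain on each somatic trace and count threshold crossings."""
    if rate_hz != RAW_RATE_HZ:
        raise ValueError(f"expected {RAW_RATE_HZ:.0f} Hz somatic traces")
    y = _resample(np.asarray(soma_traces, dtype=float), AP_RATE_HZ,
                  in_rate=rate_hz, axis=1)
    sos = signal.butter(AP_HP_ORDER, AP_HP_CUTOFF_HZ, "highpass",
                        fs=AP_RATE_HZ, output="sos")
    y = signal.sosfiltfilt(sos, y, axis=1)
    counts = np.empty(y.shape[0], dtype=int)
    for k in range(y.shape[0]):
        counts[k], _ = detect_aps(TimeSeries(y[k], AP_RATE_HZ, t0_s),
                                  threshold=threshold)
    return counts


def save_timeseries_h5(path, raw20k: Optional[TimeSeries] = None,
                       lfp1k: Optional[TimeSeries] = None,
                       apsig5k: Optional[TimeSeries] = None) -> None:
    """HDF5 export: datasets /raw20k, /lfp1k, /apsig5k with rate/t0 attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, ts in (("raw20k", raw20k), ("lfp1k", lfp1k), ("apsig5k", apsig5k)):
            if ts is None:
                continue
            d = f.create_dataset(name, data=ts.samples)
            d.attrs["rate_hz"] = ts.rate_hz
            d.attrs["t0_s"] = ts.t0_s
            d.attrs["units"] = "model units"


def load_timeseries_h5(path, name: str) -> TimeSeries:
    import h5py

    with h5py.File(path, "r") as f:
        d = f[name]
        return TimeSeries(d[...], float(d.attrs["rate_hz"]), float(d.attrs["t0_s"]))
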