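"""Synthetic fixtures with known ground truth for validating each stage.

These are first-class generators, not test scaffolding: an AR process with
known coefficients for the spectral layer, the closed-form RC step
response for the integrator, and a constructed spike train for the
detection chain.
"""

from __future__ import annotations

import math

import numpy as np

from .recording import RAW_RATE_HZ, TimeSeries
from .spectral_stats import simulate_ar

__all__ = ["gen_ar_fixture", "gen_passive_fixture", "gen_spike_fixture"]


def gen_ar_fixture(coefficients, noise_sd: float, n: int, seed: int) -> np.ndarray:
    """Seeded AR series x_t = −Σ a_k x_{t−k} + ε; burn-in 10·order discarded.

    Coefficients use the denominator convention of the spectral layer; pass
    [] for white noise.
    """
    rng = np.random.default_rng(seed)
    return simulate_ar(np.asarray(coefficients, dtype=float), noise_sd, n, rng)


def gen_passive_fixture(rm_ohm_m2: float, cm_f_m2: float, i_step_a: float,
                        area_m2: float = 1e-9, e_leak_v: float = -0.070,
                        duration_s: float = 0.1,
                        rate_hz: float = RAW_RATE_HZ) -> TimeSeries:
    """Closed-form RC response of one passive compartment to a current step.

    V(t) = E_leak + I·R·(1 − exp(−t/τ)), R = Rm/area, τ = Rm·Cm — the
    analytic oracle the exponential-Euler integrator must match exactly.
    """
    if rm_ohm_m2 <= 0 or cm_f_m2 <= 0 or area_m2 <= 0:
        raise ValueError("parameters must be positive")
    r_total = rm_ohm_m2 / area_m2
    tau = rm_ohm_m2 * cm_f_m2
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    v = e_leak_v + i_step_a * r_total * (1.0 - np.exp(-t / tau))
    return TimeSeries(v, rate_hz)


def gen_spike_fixture(n_events: int, spacing_ms: float, amplitude: float,
                      rate_hz: float = RAW_RATE_HZ,
                      start_ms: float = 50.0) -> TimeSeries:
    """20 kHz series with biphasic ~1 ms transients of a set amplitude."""
    if n_events < 0:
        raise ValueError("n_events must be ≥ 0")
    if n_events > 1 and spacing_ms <= 2.0:
        raise ValueError("spacing must exceed the 2 ms lockout")
    dur_ms = start_ms * 2 + max(n_events, 1) * spacing_ms
    n = int(round(dur_ms * 1e-3 * rate_hz))
    x = np.zeros(n)
    # biphasic waveform: 0.5 ms positive lobe, 0.5 ms negative half-lobe
    half = int(round(0.5e-3 * rate_hz))
    t = np.arange(half) / half
    wave = np.concatenate([np.sin(np.pi * t), -0.5 * np.sin(np.pi * t)])
    for k in range(n_events):
        i0 = int(round((start_ms + k * spacing_ms) * 1e-3 * rate_hz))
        x[i0:i0 + len(wave)] += amplitude * wave
    return TimeSeries(x, rate_hz)
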