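"""Baseline correction, condition averaging, delta/theta FIR separation.

Feedback-locked ERP components overlap in time: the P3-like wave rides on
delta (< ~3 Hz) while the reward-positivity / feedback-negativity complex is
theta-band (4-7.5 Hz) activity. The two are pulled apart with linear-phase
windowed-sinc FIR filters applied to the full-length subject ERP, after which
the analysis is narrowed to the 200-300 ms post-feedback window:

* delta: low-pass, 3 Hz passband edge, 2 Hz transition (-6 dB at 4.00 Hz);
* theta: band-pass 4-7.5 Hz, 2 Hz transitions (-6 dB at 3.00 and 8.50 Hz).

Both use a Hamming taper (~0.0194 passband ripple, 53 dB sidelobe floor) with
the standard length rule of 3.3 / transition-bandwidth seconds, rounded up to
an odd tap count, and are applied zero-phase by centred convolution of the
symmetric kernel over a reflect-padded signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin, freqz

from .data_model import EpochSet, SubjectERP

#: seconds-of-kernel per Hz of transition bandwidth for a Hamming design
HAMMING_LENGTH_FACTOR = 3.3
HAMMING_STOPBAND_DB = 53.0
MINUS6_DB = 20.0 * np.log10(0.5)  # -6.0206 dB, the half-amplitude point


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Windowed time-domain (windowed-sinc) FIR specification.

    ``cutoffs_hz`` are *passband edges*; the -6 dB (half-amplitude) points sit
    half a transition bandwidth outside them.
    """

    kind: str  # "lowpass" | "bandpass"
    cutoffs_hz: tuple[float, ...]
    srate: float
    transition_bw_hz: float = 2.0
    window: str = "hamming"
    zero_phase: bool = True
    label: str | None = None  # band name stamped onto filtered ERPs

    def __post_init__(self):
        if self.kind not in ("lowpass", "bandpass"):
            raise FilterDesignError(f"unsupported filter kind {self.kind!r}")
        n = {"lowpass": 1, "bandpass": 2}[self.kind]
        cuts = tuple(float(c) for c in np.atleast_1d(self.cutoffs_hz))
        object.__setattr__(self, "cutoffs_hz", cuts)
        if len(cuts) != n:
            raise FilterDesignError(f"{self.kind} needs {n} cutoff(s)")
        nyq = self.srate / 2.0
        if not all(0 < c < nyq for c in cuts):
            raise FilterDesignError(f"cutoffs {cuts} outside (0, {nyq}) Hz")
        if self.transition_bw_hz <= 0:
            raise FilterDesignError("transition bandwidth must be positive")

    @property
    def minus6db_hz(self) -> tuple[float, ...]:
        """Design -6 dB points: passband edges widened by half a transition."""
        half = self.transition_bw_hz / 2.0
        if self.kind == "lowpass":
            return (self.cutoffs_hz[0] + half,)
        lo, hi = self.cutoffs_hz
        return (lo - half, hi + half)


def delta_spec(srate: float = 256.0) -> FilterSpec:
    """Low-pass isolating delta: 3 Hz edge, -6 dB at 4.00 Hz."""
    return FilterSpec("lowpass", (3.0,), srate, label="delta")


def theta_spec(srate: float = 256.0) -> FilterSpec:
    """Band-pass isolating theta: 4-7.5 Hz, -6 dB at 3.00 / 8.50 Hz."""
    return FilterSpec("bandpass", (4.0, 7.5), srate, label="theta")


def design_fir(spec: FilterSpec) -> np.ndarray:
    """Design the linear-phase FIR kernel for ``spec``.

    Length = ceil(3.3 / transition_bw * srate), forced odd so the kernel has
    an exact centre tap and can be applied with zero delay.
    """
    m6 = spec.minus6db_hz
    nyq = spec.srate / 2.0
    half = spec.transition_bw_hz / 2.0
    edges = [m6[0] - half] if spec.kind == "lowpass" else \
        [m6[0] - half, m6[1] + half]
    if edges[0] < 0 or edges[-1] > nyq:
        raise FilterDesignError(
            f"transition band {edges} crosses 0 or Nyquist ({nyq} Hz)"
        )
    numtaps = int(np.ceil(HAMMING_LENGTH_FACTOR / spec.transition_bw_hz
                          * spec.srate))
    numtaps |= 1  # odd
    h = firwin(numtaps, list(m6), fs=spec.srate, window=spec.window,
               pass_zero=(spec.kind == "lowpass"))
    assert np.allclose(h, h[::-1]), "windowed-sinc kernel must be symmetric"
    return h


# ---------------------------------------------------------------------------
# response measurement (audit / acceptance)
# ---------------------------------------------------------------------------

def frequency_response(h: np.ndarray, srate: float,
                       n: int = 1 << 18) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response in dB on a dense frequency grid."""
    w, resp = freqz(h, worN=n, fs=srate)
    mag_db = 20.0 * np.log10(np.maximum(np.abs(resp), 1e-30))
    return w, mag_db


def measure_minus6db(h: np.ndarray, srate: float,
                     spec: FilterSpec) -> tuple[float, ...]:
    """Measured -6 dB crossing frequencies, one per design edge."""
    w, mag = frequency_response(h, srate)
    out = []
    for edge in spec.minus6db_hz:
        # search the transition region around the design edge
        lo = max(edge - spec.transition_bw_hz, 0.0)
        hi = min(edge + spec.transition_bw_hz, srate / 2.0)
        sel = (w >= lo) & (w <= hi)
        ws, ms = w[sel], mag[sel]
        diff = ms - MINUS6_DB
        sign = np.sign(diff)
        crossings = np.nonzero(np.diff(sign))[0]
        if len(crossings) == 0:
            raise FilterDesignError(f"no -6 dB crossing near {edge} Hz")
        # crossing closest to the design edge, linearly interpolated
        best = min(crossings, key=lambda i: abs(ws[i] - edge))
        f0, f1 = ws[best], ws[best + 1]
        d0, d1 = diff[best], diff[best + 1]
        out.append(float(f0 + (f1 - f0) * d0 / (d0 - d1)))
    return tuple(out)


def measure_stopband_attenuation(h: np.ndarray, srate: float,
                                 spec: FilterSpec) -> float:
    """Minimum attenuation (dB) over the stopband(s).

    The nominal stopband edge is one transition bandwidth outside the
    passband edge; the roll-off is still descending there, so the stopband is
    taken to start at the first magnitude-response null at/after that edge
    and the minimum attenuation over the sidelobe region beyond is reported.
    """
    w, mag = frequency_response(h, srate)
    nyq = srate / 2.0
    if spec.kind == "lowpass":
        bands = [(spec.cutoffs_hz[0] + spec.transition_bw_hz, nyq)]
    else:
        lo, hi = spec.cutoffs_hz
        bands = [(0.0, max(lo - spec.transition_bw_hz, 0.0)),
                 (hi + spec.transition_bw_hz, nyq)]
    worst = np.inf
    for start, stop in bands:
        if stop - start <= 0:
            continue
        sel = (w >= start) & (w <= stop)
        ws, ms = w[sel], mag[sel]
        if start > 0.0 and stop == nyq:  # upper stopband: skip roll-off tail
            mins = np.nonzero((ms[1:-1] < ms[:-2]) & (ms[1:-1] < ms[2:]))[0]
            if len(mins):
                ws, ms = ws[mins[0] + 1:], ms[mins[0] + 1:]
        elif stop < nyq:  # lower stopband: trim the tail ascending to passband
            mins = np.nonzero((ms[1:-1] < ms[:-2]) & (ms[1:-1] < ms[2:]))[0]
            if len(mins):
                ws, ms = ws[:mins[-1] + 2], ms[:mins[-1] + 2]
        worst = min(worst, -float(ms.max()))
    return worst


def measure_passband_ripple(h: np.ndarray, srate: float,
                            spec: FilterSpec) -> float:
    """Maximum linear-amplitude deviation from unit gain inside the passband."""
    w, mag = frequency_response(h, srate)
    if spec.kind == "lowpass":
        sel = w <= spec.cutoffs_hz[0]
    else:
        sel = (w >= spec.cutoffs_hz[0]) & (w <= spec.cutoffs_hz[1])
    amp = 10.0 ** (mag[sel] / 20.0)
    return float(np.abs(amp - 1.0).max())


def describe_filter(spec: FilterSpec) -> dict:
    """Designed + measured characteristics, for audit output."""
    h = design_fir(spec)
    return {
        "kind": spec.kind,
        "label": spec.label,
        "passband_edges_hz": list(spec.cutoffs_hz),
        "transition_bw_hz": spec.transition_bw_hz,
        "srate": spec.srate,
        "n_taps": int(len(h)),
        "design_minus6db_hz": list(spec.minus6db_hz),
        "measured_minus6db_hz": [round(f, 4) for f in
                                 measure_minus6db(h, spec.srate, spec)],
        "measured_stopband_attenuation_db": round(
            measure_stopband_attenuation(h, spec.srate, spec), 2),
        "measured_passband_ripple": round(
            measure_passband_ripple(h, spec.srate, spec), 4),
    }


# ---------------------------------------------------------------------------
# ERP operations
# ---------------------------------------------------------------------------

def ms_to_sample(t_ms: float, t0: float, srate: float) -> int:
    """Documented ms -> sample convention: round((t - t0) * srate / 1000)."""
    return int(round((t_ms - t0) * srate / 1000.0))


@dataclass(frozen=True)
class AnalysisWindow:
    start_ms: float = 200.0
    end_ms: float = 300.0

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")

    def sample_slice(self, t0: float, srate: float, n_samples: int) -> slice:
        a = ms_to_sample(self.start_ms, t0, srate)
        b = ms_to_sample(self.end_ms, t0, srate)
        if a < 0 or b > n_samples or a >= b:
            raise ValueError(
                f"window [{self.start_ms}, {self.end_ms}) ms maps to samples "
                f"[{a}, {b}) outside 0..{n_samples}"
            )
        return slice(a, b)


BASELINE_MS = (-250.0, 0.0)


def baseline_correct(obj: EpochSet | SubjectERP,
                     interval: tuple[float, float] = BASELINE_MS):
    """Subtract the mean over the pre-feedback ``interval`` per channel.

    Works on trial tensors and on averaged ERPs; idempotent by construction.
    """
    n = obj.data.shape[-1]
    a = ms_to_sample(interval[0], obj.t0, obj.srate)
    b = ms_to_sample(interval[1], obj.t0, obj.srate)
    if a < 0 or b > n or a >= b:
        raise ValueError(f"baseline interval {interval} ms outside epoch span")
    base = obj.data[..., a:b].mean(axis=-1, keepdims=True)
    return replace(obj, data=obj.data - base)


MIN_TRIALS = 5  # subjects with fewer artifact-free trials per valence drop out


class InsufficientTrialsError(ValueError):
    def __init__(self, subject_id: str, valence: str, n: int):
        self.subject_id, self.valence, self.n = subject_id, valence, n
        super().__init__(
            f"subject {subject_id}: only {n} {valence} trials "
            f"(minimum {MIN_TRIALS})"
        )


def average_by_condition(epochs: EpochSet,
                         min_trials: int = MIN_TRIALS
                         ) -> dict[str, SubjectERP]:
    """Arithmetic trial mean per valence -> broadband SubjectERPs."""
    out = {}
    for valence in ("positive", "negative"):
        trials = epochs.trials_for(valence)
        if trials.shape[0] < min_trials:
            raise InsufficientTrialsError(epochs.subject_id, valence,
                                          trials.shape[0])
        out[valence] = SubjectERP(
            subject_id=epochs.subject_id, valence=valence, band="broadband",
            data=trials.mean(axis=0), srate=epochs.srate, t0=epochs.t0,
            montage=epochs.montage,
        )
    return out


def filter_array(data: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-phase filtering along the last axis.

    The symmetric odd-length kernel is convolved once over a reflect-padded
    signal, so the output has zero group delay in the passband without the
    squared response of forward-backward filtering.
    """
    half = len(h) // 2
    padded = np.concatenate(
        [data[..., 1:half + 1][..., ::-1], data,
         data[..., -half - 1:-1][..., ::-1]], axis=-1)
    return fftconvolve(padded, h[(np.newaxis,) * (data.ndim - 1)],
                       mode="valid", axes=-1)


def apply_filter(erp: SubjectERP, spec: FilterSpec) -> SubjectERP:
    """Filter a broadband subject ERP into the band named by ``spec.label``."""
    if erp.band != "broadband":
        raise ValueError(
            f"refusing to re-filter ERP already in band {erp.band!r}"
        )
    if abs(spec.srate - erp.srate) > 1e-9:
        raise ValueError("filter srate does not match ERP srate")
    band = spec.label or ("delta" if spec.kind == "lowpass" else "theta")
    h = design_fir(spec)
    return replace(erp, data=filter_array(erp.data, h), band=band)


def extract_window(erp: SubjectERP,
                   window: AnalysisWindow = AnalysisWindow()) -> np.ndarray:
    """channels x samples matrix over the half-open analysis window."""
    sl = window.sample_slice(erp.t0, erp.srate, erp.data.shape[1])
    return erp.data[:, sl]


def erp_amplitude_feature(erp: SubjectERP, channel: str = "FCz",
                          window: AnalysisWindow = AnalysisWindow()) -> float:
    """Mean amplitude (µV) over the window at one electrode.

    On the positive-feedback ERP this is the reward positivity (RewP); on the
    negative-feedback ERP, the feedback-related negativity (FRN).
    """
    idx = erp.montage.index(channel)
    return float(extract_window(erp, window)[idx].mean())


def band_erps(erp: SubjectERP,
              specs: Sequence[FilterSpec] | None = None) -> dict[str, SubjectERP]:
    """Convenience: broadband ERP -> {'delta': ..., 'theta': ...}."""
    if specs is None:
        specs = (delta_spec(erp.srate), theta_spec(erp.srate))
    out = {}
    for spec in specs:
        filtered = apply_filter(erp, spec)
        out[filtered.band] = filtered
    return out
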