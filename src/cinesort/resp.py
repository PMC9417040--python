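"""Respiratory surrogate signal analysis.

Retrospective phase assignment, representative-signal modelling and the
normalised amplitude/phase error terms used by the sorting cost function.

The surrogate signal is the externally measured breathing trace (an RPM-style
marker displacement). Phase is assigned retrospectively by equally dividing
every peak-to-peak interval: phase 0 at each end-inhale maximum, increasing
linearly to 1 over the cycle. A *representative signal* — a truncated
sinusoidal series in phase — is least-squares fitted to the (phase, amplitude)
cloud of CT acquisition points and serves as the reference from which
amplitude errors are measured.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    FlatTraceError,
    InsufficientCyclesError,
    RankDeficiencyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RespiratoryTrace",
    "RepresentativeSignal",
    "detect_peaks",
    "assign_phase",
    "phase_at",
    "fit_representative",
    "amplitude_error",
    "phase_error",
]


@dataclass
class RespiratoryTrace:
    """A sampled surrogate breathing signal.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing.
    amplitude:
        Surrogate amplitude in arbitrary units (marker displacement analogue).
    internal:
        Optional ground-truth internal motion channel (simulation only).
        Units are whatever the producer chose; the phantom simulator stores
        millimetres of superior–inferior displacement.
    peaks:
        Indices of detected end-inhale maxima (``None`` until detected).
    phase:
        Per-sample phase in ``[0, 1)``; NaN outside the first/last peak
        (``None`` until assigned).
    """

    time: np.ndarray
    amplitude: np.ndarray
    internal: np.ndarray | None = None
    peaks: np.ndarray | None = None
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.amplitude.shape:
            raise ValueError("time and amplitude must be 1-D and equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.internal is not None:
            self.internal = np.asarray(self.internal, dtype=float)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def peak_times(self) -> np.ndarray:
        if self.peaks is None:
            raise InsufficientCyclesError("peaks have not been detected")
        return self.time[self.peaks]

    def amplitude_at(self, t) -> np.ndarray:
        """Linear interpolation of the surrogate at arbitrary times."""
        return np.interp(np.asarray(t, dtype=float), self.time, self.amplitude)

    def internal_at(self, t) -> np.ndarray:
        if self.internal is None:
            raise ValueError("trace carries no internal ground-truth channel")
        return np.interp(np.asarray(t, dtype=float), self.time, self.internal)

    # -- serialisation --------------------------------------------------
    def to_csv(self, path) -> None:
        cols = {"time_s": self.time, "amplitude": self.amplitude}
        if self.internal is not None:
            cols["internal_mm"] = self.internal
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "RespiratoryTrace":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "amplitude" not in df.columns:
            raise ValueError("trace CSV must have columns time_s,amplitude")
        internal = df["internal_mm"].to_numpy() if "internal_mm" in df.columns else None
        return cls(df["time_s"].to_numpy(), df["amplitude"].to_numpy(), internal=internal)


def detect_peaks(
    trace: RespiratoryTrace,
    min_separation: float = 1.0,
    noise_sigmas: float = 5.0,
) -> np.ndarray:
    """Locate end-inhale maxima of the surrogate.

    Maxima must be separated by at least ``min_separation`` seconds and have
    a prominence of at least ``noise_sigmas`` times the robust sensor-noise
    estimate (median absolute successive difference). Referencing the noise
    level rather than the session amplitude range keeps genuine cycles whose
    depth has drifted far below the deepest one while still rejecting noise
    ripples, whose prominence scales with the sensor noise.

    Returns the peak indices and stores them on the trace.

    Raises
    ------
    InsufficientCyclesError
        If fewer than two peaks are found (phase is then undefined).
    """
    x = trace.amplitude
    ptp = float(np.ptp(x))
    if ptp <= 0:
        raise InsufficientCyclesError("constant trace: no breathing cycles")
    distance = max(1, int(round(min_separation * trace.sample_rate)))
    # robust noise scale; successive differences remove the slow breathing
    # component, the 1.4826 factor calibrates the MAD to a standard deviation
    sigma = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    floor = max(noise_sigmas * sigma, 1e-12 * ptp)
    peaks, _ = find_peaks(x, distance=distance, prominence=floor)
    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"found {len(peaks)} peak(s); need >= 2 for phase assignment"
        )
    trace.peaks = peaks
    return peaks


def phase_at(peak_times: np.ndarray, t) -> np.ndarray:
    """Phase of arbitrary times given the end-inhale peak times.

    Within the cycle ``[p_j, p_{j+1})`` the phase grows linearly from 0 to 1.
    Times outside ``[first peak, last peak]`` get NaN (phase undefined there);
    a time exactly at the last peak maps to phase 0.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ph = np.full(t.shape, np.nan)
    inside = (t >= peak_times[0]) & (t < peak_times[-1])
    if inside.any():
        idx = np.searchsorted(peak_times, t[inside], side="right") - 1
        p0 = peak_times[idx]
        p1 = peak_times[idx + 1]
        ph[inside] = (t[inside] - p0) / (p1 - p0)
    ph[t == peak_times[-1]] = 0.0
    return ph


def assign_phase(trace: RespiratoryTrace, peaks: np.ndarray | None = None) -> np.ndarray:
    """Per-sample phase by equal division of every peak-to-peak interval."""
    if peaks is None:
        if trace.peaks is None:
            detect_peaks(trace)
        peaks = trace.peaks
    if peaks is None or len(peaks) < 2:
        raise InsufficientCyclesError("need >= 2 peaks to assign phase")
    phase = phase_at(trace.time[peaks], trace.time)
    trace.peaks = np.asarray(peaks)
    trace.phase = phase
    n_undef = int(np.isnan(phase).sum())
    if n_undef:
        logger.debug("%d samples outside [first peak, last peak]: phase undefined", n_undef)
    return phase


@dataclass(frozen=True)
class RepresentativeSignal:
    """Truncated sinusoidal series amplitude(phase), 1-periodic in phase.

    ``amplitude(p) = a0 + sum_k a[k-1] cos(2 pi k p) + b[k-1] sin(2 pi k p)``
    for ``k = 1..K``.
    """

    K: int
    a0: float
    a: np.ndarray = field(default_factory=lambda: np.zeros(0))
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual_rms: float = 0.0

    def __call__(self, phase) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full(phase.shape, self.a0, dtype=float)
        for k in range(1, self.K + 1):
            w = 2.0 * np.pi * k * phase
            out = out + self.a[k - 1] * np.cos(w) + self.b[k - 1] * np.sin(w)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "K": self.K,
                    "a0": self.a0,
                    "a": list(map(float, self.a)),
                    "b": list(map(float, self.b)),
                    "residual_rms": self.residual_rms,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "RepresentativeSignal":
        with open(path) as fh:
            d = json.load(fh)
        return cls(int(d["K"]), float(d["a0"]), np.asarray(d["a"], dtype=float),
                   np.asarray(d["b"], dtype=float), float(d["residual_rms"]))


def fit_representative(phases, amplitudes, K: int = 2) -> RepresentativeSignal:
    """Least-squares fit of the K-harmonic series to (phase, amplitude) points.

    The points are the CT acquisition points of a study pooled over all couch
    positions. ``K = 0`` degenerates to the mean amplitude.

    Raises
    ------
    RankDeficiencyError
        If the design matrix is rank deficient (phases too clustered for the
        requested number of harmonics).
    """
    phases = np.asarray(phases, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    ok = np.isfinite(phases) & np.isfinite(amplitudes)
    phases, amplitudes = phases[ok], amplitudes[ok]
    n_coef = 2 * K + 1
    if len(phases) < n_coef:
        raise RankDeficiencyError(
            f"need >= {n_coef} points for K={K} harmonics, got {len(phases)}"
        )
    cols = [np.ones_like(phases)]
    for k in range(1, K + 1):
        w = 2.0 * np.pi * k * phases
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, amplitudes, rcond=None)
    if rank < n_coef:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {n_coef}: phases clustered; try fewer harmonics"
        )
    resid = amplitudes - X @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    a = coef[1::2] if K else np.zeros(0)
    b = coef[2::2] if K else np.zeros(0)
    return RepresentativeSignal(K=K, a0=float(coef[0]), a=np.asarray(a), b=np.asarray(b),
                                residual_rms=rms)


def amplitude_error(
    amplitude,
    phase,
    ref: RepresentativeSignal,
    rpm_min: float,
    rpm_max: float,
) -> np.ndarray:
    """Normalised amplitude error of acquisition points.

    ``|RPM(x) - REF(phase(x))| / (max(RPM) - min(RPM))`` as a fraction in
    [0, 1]. ``rpm_min``/``rpm_max`` are taken over the acquisition-point
    population (the plotted cloud the reference was fitted to). Values beyond
    1 are clipped and the clipping is logged.
    """
    rng = float(rpm_max) - float(rpm_min)
    if rng <= 0:
        raise FlatTraceError("amplitude range is zero: amplitude error undefined")
    err = np.abs(np.asarray(amplitude, dtype=float) - ref(phase)) / rng
    n_clip = int(np.sum(err > 1.0))
    if n_clip:
        logger.warning("clipped %d amplitude error(s) > 1 to 1", n_clip)
    return np.clip(err, 0.0, 1.0)


def phase_error(phase, bin_centre) -> np.ndarray:
    """Normalised circular phase error in [0, 1].

    The circular distance ``d = min(|p - c|, 1 - |p - c|)`` has a maximum of
    0.5 (antipodal phases); it is doubled so the theoretical maximum maps to
    1, putting the phase term on the same [0, 1] scale as the amplitude and
    RMA terms of the sorting cost.
    """
    p = np.asarray(phase, dtype=float) % 1.0
    c = np.asarray(bin_centre, dtype=float) % 1.0
    d = np.abs(p - c)
    d = np.minimum(d, 1.0 - d)
    return 2.0 * d


def acquisition_phase_amplitude(trace: RespiratoryTrace, times) -> tuple[np.ndarray, np.ndarray]:
    """Phase and surrogate amplitude at CT acquisition instants.

    Detects peaks / assigns phase on the trace if not already done.
    """
    if trace.peaks is None:
        detect_peaks(trace)
    phases = phase_at(trace.peak_times, times)
    amps = trace.amplitude_at(times)
    return phases, amps
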