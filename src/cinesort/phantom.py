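"""Synthetic breathing torso and cine-mode 4DCT acquisition simulator.

The phantom is analytic: an elliptical body whose cross-section tapers
slowly with z, a bright spine, two low-density lungs, a diaphragm dome whose
apex translates superior–inferior with internal motion, and a Gaussian
nodule riding on the diaphragm. A deterministic smooth intensity texture is
added inside the body so every slice has in-mask variance. Voxel values are
HU-like (air -1000, lung ~ -800, soft tissue ~ 30-40, spine 250).

Breathing is quasi-periodic: per-cycle period jitter, a lognormal random
walk on per-cycle amplitude, linear baseline drift, and additive sensor
noise. The internal (organ) motion is a mixture of the lagged surrogate and
an independent smooth breathing-like process, controlled by a correlation
parameter — the two failure modes that create residual motion artifacts
(irregular breathing; imperfect surrogate–organ correlation).

Coordinates: z increases superior -> inferior, in mm; slice index 0 of a
block is its most superior slice; pixel grids are 0-based with the field of
view centred on the body axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InsufficientCyclesError, PhantomSupportError
from .resp import RespiratoryTrace

__all__ = [
    "BreathingParams",
    "AcquisitionConfig",
    "CineStudy",
    "generate_trace",
    "render_phantom",
    "simulate_bh_scan",
    "simulate_cine_scan",
    "body_ellipse_mask",
    "diaphragm_apex_z",
]

# Fixed phantom geometry (mm). The phantom supports z in [0, Z_SUPPORT].
Z_SUPPORT = 200.0
FOV_MM = 320.0
_BODY_A0 = 140.0                    # lateral semi-axis (mm)
_BODY_B0 = 105.0                    # antero-posterior semi-axis (mm)
_SPINE = (0.0, 70.0, 18.0, 14.0, 250.0)          # (cx, cy, ax, ay, value)
_LUNG_CX, _LUNG_CY = 62.0, -10.0                  # mirrored at +-x
_LUNG_AX, _LUNG_AY, _LUNG_AZ = 48.0, 62.0, 52.0
_LUNG_CZ = 55.0
_DOME_APEX_Z0 = 95.0                              # diaphragm apex at rest
_DOME_CURV = 1.0 / 80.0                           # z_dome = apex + r^2 * curv
_LESION_CX, _LESION_CY, _LESION_CZ0 = 62.0, -10.0, 60.0
_LESION_SIGMA_XY, _LESION_SIGMA_Z = 7.0, 12.0
_HU_AIR, _HU_LUNG, _HU_TISSUE, _HU_ABDOMEN, _HU_LESION = -1000.0, -800.0, 40.0, 30.0, 45.0
_TEX_AMP = 25.0
_MAX_DISPLACEMENT = 20.0


@dataclass(frozen=True)
class BreathingParams:
    """Parameters of the quasi-periodic breathing model.

    ``surrogate_internal_correlation`` mixes the (lagged) surrogate with an
    independent smooth process to form the internal motion: 1 means the
    surrogate tracks the organs perfectly, 0 means it carries no information
    about them.
    """

    mean_period: float = 4.0            # s
    period_jitter_sd: float = 0.4       # s, per-cycle
    mean_amplitude: float = 10.0        # arbitrary surrogate units
    amplitude_drift_sd: float = 0.15    # lognormal step sd per cycle
    baseline_drift_rate: float = 0.02   # units / s
    noise_sd: float = 0.2               # units
    surrogate_internal_correlation: float = 0.9
    internal_lag: float = 0.0           # s, surrogate leads internal by this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ConfigError("mean_period must be > 0")
        for name in ("period_jitter_sd", "mean_amplitude", "amplitude_drift_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.surrogate_internal_correlation <= 1.0:
            raise ConfigError("surrogate_internal_correlation must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Cine acquisition geometry.

    Defaults mirror a clinical cine protocol: 8 slices of 2.5 mm per couch
    position, ~0.3 s cine interval, 4–5 s of cine per couch position (at
    least one breathing cycle), 10 reconstructed phase bins.
    """

    n_couch: int = 10
    m_per_couch: int = 15
    slices_per_block: int = 8
    slice_thickness: float = 2.5        # mm
    cine_interval: float = 0.3          # s
    cine_duration: float = 4.5          # s per couch position
    pixel_grid: tuple[int, int] = (64, 64)
    n_phase_bins: int = 10

    def __post_init__(self) -> None:
        for name in ("n_couch", "m_per_couch", "slices_per_block", "n_phase_bins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.slice_thickness <= 0 or self.cine_interval <= 0:
            raise ConfigError("slice_thickness and cine_interval must be > 0")
        if self.cine_duration < (self.m_per_couch - 1) * self.cine_interval:
            raise ConfigError(
                "cine_duration must cover (m_per_couch - 1) * cine_interval"
            )

    @property
    def block_extent(self) -> float:
        return self.slices_per_block * self.slice_thickness

    @property
    def z_extent(self) -> float:
        return self.n_couch * self.block_extent

    @property
    def pixel_spacing(self) -> float:
        return FOV_MM / self.pixel_grid[0]


@dataclass
class CineStudy:
    """An oversampled cine acquisition.

    ``blocks`` has shape (n_couch, m_per_couch, slices_per_block, rows, cols);
    ``timestamps`` (n, m) holds the mid-acquisition instant of each block and
    ``ground_truth_internal`` (n, m) the internal displacement (mm) the
    phantom was frozen at. A breath-hold study has m_per_couch = 1 and no
    trace.
    """

    blocks: np.ndarray
    timestamps: np.ndarray
    couch_z_origins: np.ndarray
    config: AcquisitionConfig
    trace: RespiratoryTrace | None = None
    ground_truth_internal: np.ndarray | None = None
    body_region: str = "thorax"

    def __post_init__(self) -> None:
        n, m = self.blocks.shape[:2]
        if self.timestamps.shape != (n, m):
            raise ConfigError("timestamps shape must match (n_couch, m_per_couch)")
        for i in range(n):
            if m > 1 and not np.all(np.diff(self.timestamps[i]) > 0):
                raise ConfigError(f"timestamps not strictly increasing at couch {i}")
        if self.trace is not None:
            t0, t1 = self.trace.time[0], self.trace.time[-1]
            if self.timestamps.min() < t0 or self.timestamps.max() > t1:
                raise ConfigError("block timestamps outside trace time support")

    @property
    def n_couch(self) -> int:
        return self.blocks.shape[0]

    @property
    def m_per_couch(self) -> int:
        return self.blocks.shape[1]


def diaphragm_apex_z(displacement: float) -> float:
    """z of the diaphragm dome apex at a given internal displacement (mm)."""
    return _DOME_APEX_Z0 + displacement


def body_ellipse_mask(z: float, config: AcquisitionConfig) -> np.ndarray:
    """Analytic in-body support of the slice at height z (oracle for masks)."""
    xx, yy = _pixel_coords(config)
    return (xx / _BODY_A0) ** 2 + (yy / _BODY_B0) ** 2 <= 1.0


def _pixel_coords(config: AcquisitionConfig) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = config.pixel_grid
    sp = config.pixel_spacing
    x = (np.arange(cols) - (cols - 1) / 2.0) * sp
    y = (np.arange(rows) - (rows - 1) / 2.0) * sp
    return np.meshgrid(x, y)


def _soft(q: np.ndarray, eps: float) -> np.ndarray:
    """Partial-volume edge: 1 inside (q <= 0), 0 outside, linear ramp of
    width ``eps`` in the units of q. Mimics CT partial-volume averaging and
    keeps slice-to-slice differences smooth instead of flipping whole
    pixels."""
    return np.clip(0.5 - q / eps, 0.0, 1.0)


def _render_slice(z: float, displacement: float, config: AcquisitionConfig) -> np.ndarray:
    xx, yy = _pixel_coords(config)

    q_body = (xx / _BODY_A0) ** 2 + (yy / _BODY_B0) ** 2 - 1.0
    w_body = _soft(q_body, 0.10)

    scx, scy, sax, say, sval = _SPINE
    q_spine = ((xx - scx) / sax) ** 2 + ((yy - scy) / say) ** 2 - 1.0
    w_spine = _soft(q_spine, 0.15)

    # travelling-wave textures: their adjacent-slice RMS difference is
    # uniform in z because the z-advance only shifts the in-plane phase.
    # Several wavelengths emulate organ/vessel-scale heterogeneity.
    tex = (_TEX_AMP
           * np.sin(2.0 * np.pi * (xx / 47.0 + z / 40.0))
           * np.cos(2.0 * np.pi * yy / 61.0))
    tex_fine = (18.0 * np.sin(2.0 * np.pi * (yy / 53.0 - z / 31.0))
                * np.cos(2.0 * np.pi * xx / 71.0)
                + 12.0 * np.sin(2.0 * np.pi * (xx / 29.0 + yy / 37.0 + z / 23.0)))

    inside = _HU_TISSUE + tex + 0.5 * tex_fine
    inside = inside + w_spine * (sval - _HU_TISSUE)

    # lungs: elliptical cylinders in z, capped inferiorly by the soft
    # diaphragm dome (a cylinder keeps the slice-to-slice change rate of the
    # cross-section uniform, as gradual real anatomy is)
    dome_apex = diaphragm_apex_z(displacement)
    for sx in (-1.0, 1.0):
        cx = sx * _LUNG_CX
        q_lung = (((xx - cx) / _LUNG_AX) ** 2
                  + ((yy - _LUNG_CY) / _LUNG_AY) ** 2) - 1.0
        w_lung = _soft(q_lung, 0.15)
        r2 = (xx - cx) ** 2 + (yy - _LUNG_CY) ** 2
        dome_z = dome_apex + r2 * _DOME_CURV
        # smooth split of the lung envelope at the diaphragm surface; the
        # tanh width (~12 mm) keeps the slice-to-slice change rate gradual
        # relative to the slice spacing
        w_air = 0.5 * (1.0 - np.tanh((z - dome_z) / 6.0))
        lung_val = w_air * _HU_LUNG + (1.0 - w_air) * _HU_ABDOMEN
        inside = inside + w_lung * (lung_val + 0.3 * tex + tex_fine - inside)

    # lesion as a Gaussian nodule: infinitely smooth in z, so it has no
    # pole/equator kinks at the slice-spacing scale
    lz = _LESION_CZ0 + displacement
    w_les = np.exp(-(((xx - _LESION_CX) ** 2 + (yy - _LESION_CY) ** 2)
                     / (2.0 * _LESION_SIGMA_XY**2)
                     + (z - lz) ** 2 / (2.0 * _LESION_SIGMA_Z**2)))
    inside = inside + w_les * (_HU_LESION - inside)

    img = _HU_AIR + w_body * (inside - _HU_AIR)
    return img.astype(np.float32)


def render_phantom(
    displacement: float,
    config: AcquisitionConfig,
    z_range: tuple[float, float],
) -> np.ndarray:
    """Voxelise the phantom frozen at one internal displacement.

    Returns a stack of shape (n_slices, rows, cols) whose slice centres tile
    ``z_range`` at the configured thickness. Deterministic: the same
    displacement yields identical pixels.
    """
    z0, z1 = z_range
    if z0 < 0 or z1 > Z_SUPPORT or z1 <= z0:
        raise PhantomSupportError(
            f"z_range {z_range} outside phantom support [0, {Z_SUPPORT}]"
        )
    if abs(displacement) > _MAX_DISPLACEMENT:
        raise PhantomSupportError(
            f"|displacement| {abs(displacement):.1f} mm exceeds {_MAX_DISPLACEMENT} mm"
        )
    n = int(round((z1 - z0) / config.slice_thickness))
    centres = z0 + (np.arange(n) + 0.5) * config.slice_thickness
    return np.stack([_render_slice(z, displacement, config) for z in centres])


def _quasi_periodic(rng: np.random.Generator, mean_period: float, jitter_sd: float,
                    mean_amp: float, drift_sd: float, t: np.ndarray,
                    t_start: float = 0.0) -> np.ndarray:
    """Breathing-shaped signal: amplitude * 0.5 * (1 + cos(2 pi u)).

    u is the continuous cycle coordinate; integer u are end-inhale peaks.
    Per-cycle periods are normal (clipped to stay positive); per-cycle
    amplitudes follow a lognormal random walk.
    """
    duration = float(t[-1]) - t_start
    n_cycles = int(np.ceil(duration / max(mean_period * 0.25, 1e-6))) + 2
    periods = rng.normal(mean_period, jitter_sd, n_cycles)
    periods = np.clip(periods, 0.25 * mean_period, 4.0 * mean_period)
    starts = t_start + np.concatenate([[0.0], np.cumsum(periods)])
    while starts[-1] < t[-1]:
        extra = float(np.clip(rng.normal(mean_period, jitter_sd),
                              0.25 * mean_period, 4.0 * mean_period))
        periods = np.append(periods, extra)
        starts = np.append(starts, starts[-1] + extra)
    amps = mean_amp * np.exp(np.cumsum(rng.normal(0.0, drift_sd, len(periods))))
    u = np.interp(t, starts, np.arange(len(starts), dtype=float))
    amps_ext = np.append(amps, amps[-1])
    a_t = np.interp(u, np.arange(len(amps_ext), dtype=float), amps_ext)
    return a_t * 0.5 * (1.0 + np.cos(2.0 * np.pi * u))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_trace(
    params: BreathingParams,
    duration: float,
    sample_rate: float = 25.0,
) -> RespiratoryTrace:
    """Sample a surrogate trace plus ground-truth internal motion.

    The internal channel is
    ``corr * z(surrogate(t - lag)) + (1 - corr) * z(independent process)``
    (z-scored components), rescaled to the surrogate's amplitude range. With
    correlation 1 and zero lag it equals the noise-free surrogate up to an
    affine map.
    """
    if duration < params.mean_period:
        raise InsufficientCyclesError(
            "duration shorter than one mean period: phase analysis impossible"
        )
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)

    clean = _quasi_periodic(rng, params.mean_period, params.period_jitter_sd,
                            params.mean_amplitude, params.amplitude_drift_sd, t)
    clean = clean + params.baseline_drift_rate * t
    surrogate = clean + rng.normal(0.0, params.noise_sd, t.shape)

    # Independent smooth process: its own breathing-like signal with a
    # perturbed period and a random phase offset, no sensor noise.
    alt_period = params.mean_period * (1.0 + rng.uniform(-0.15, 0.15))
    offset = rng.uniform(0.0, alt_period)
    indep = _quasi_periodic(rng, alt_period,
                            max(params.period_jitter_sd, 0.05 * alt_period),
                            params.mean_amplitude, params.amplitude_drift_sd,
                            t, t_start=-offset)

    lagged = np.interp(t - params.internal_lag, t, clean)
    corr = params.surrogate_internal_correlation
    mix = corr * _zscore(lagged) + (1.0 - corr) * _zscore(indep)
    smin, smax = float(surrogate.min()), float(surrogate.max())
    span = mix.max() - mix.min()
    if span > 0:
        internal = smin + (mix - mix.min()) / span * (smax - smin)
    else:
        internal = np.full_like(mix, 0.5 * (smin + smax))
    return RespiratoryTrace(time=t, amplitude=surrogate, internal=internal)


def simulate_bh_scan(config: AcquisitionConfig | None = None,
                     body_region: str = "thorax") -> CineStudy:
    """Motion-free (breath-hold) study: one candidate per couch position.

    The whole phantom at displacement 0 is partitioned into contiguous blocks
    so that block boundaries exist for extreme-value index verification.
    """
    if config is None:
        config = AcquisitionConfig()
    config = replace(config, m_per_couch=1,
                     cine_duration=max(config.cine_duration, 0.0))
    if config.z_extent > Z_SUPPORT:
        raise ConfigError(
            f"n_couch * block extent {config.z_extent} mm exceeds phantom support"
        )
    origins = np.arange(config.n_couch) * config.block_extent
    blocks = np.stack([
        render_phantom(0.0, config, (z0, z0 + config.block_extent))[None]
        for z0 in origins
    ])
    timestamps = np.zeros((config.n_couch, 1))
    gt = np.zeros((config.n_couch, 1))
    return CineStudy(blocks=blocks, timestamps=timestamps,
                     couch_z_origins=origins.astype(float), config=config,
                     trace=None, ground_truth_internal=gt,
                     body_region=body_region)


def simulate_cine_scan(
    params: BreathingParams,
    config: AcquisitionConfig | None = None,
    motion_mm: float = 8.0,
    body_region: str = "thorax",
) -> CineStudy:
    """Simulate an oversampled cine acquisition driven by the breathing model.

    At couch position i, m_per_couch snapshot blocks are acquired
    ``cine_interval`` apart; each block renders the phantom frozen at the
    internal displacement at its timestamp. The internal channel of the trace
    is mapped affinely to [-motion_mm, +motion_mm] of diaphragm displacement
    and stored in millimetres.
    """
    if config is None:
        config = AcquisitionConfig()
    if config.z_extent > Z_SUPPORT:
        raise ConfigError("acquisition z extent exceeds phantom support")
    if motion_mm < 0 or motion_mm > _MAX_DISPLACEMENT - 5:
        raise ConfigError(f"motion_mm must be in [0, {_MAX_DISPLACEMENT - 5}]")

    pad = 2.0 * params.mean_period
    duration = config.n_couch * config.cine_duration + 2 * pad
    trace = generate_trace(params, duration)

    internal = trace.internal
    centre = 0.5 * (internal.max() + internal.min())
    half = 0.5 * (internal.max() - internal.min())
    disp = motion_mm * (internal - centre) / (half if half > 0 else 1.0)
    trace = RespiratoryTrace(time=trace.time, amplitude=trace.amplitude,
                             internal=disp)

    t0 = pad
    n, m = config.n_couch, config.m_per_couch
    timestamps = (t0
                  + np.arange(n)[:, None] * config.cine_duration
                  + np.arange(m)[None, :] * config.cine_interval)
    gt = trace.internal_at(timestamps)
    origins = np.arange(n) * config.block_extent

    blocks = np.empty((n, m) + (config.slices_per_block,) + tuple(config.pixel_grid),
                      dtype=np.float32)
    for i in range(n):
        z0 = origins[i]
        for j in range(m):
            blocks[i, j] = render_phantom(float(np.clip(gt[i, j], -_MAX_DISPLACEMENT,
                                                        _MAX_DISPLACEMENT)),
                                          config, (z0, z0 + config.block_extent))
    return CineStudy(blocks=blocks, timestamps=timestamps,
                     couch_z_origins=origins.astype(float), config=config,
                     trace=trace, ground_truth_internal=gt,
                     body_region=body_region)
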