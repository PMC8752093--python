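"""Synthetic two-channel photon-count traces from Brownian particles.

Particles of each fluorescent species perform an isotropic Gaussian random
walk (per-axis step variance ``2 D dt``) in a periodic cuboid that is large
compared to the confocal detection volume.  The detection profile is the
standard 3D-Gaussian molecular detection function

    MDF(r) = exp(-2 (x^2 + y^2) / omega_xy^2 - 2 z^2 / omega_z^2),

so the expected count in a time bin is the per-step sum of per-particle
brightness times MDF, plus uncorrelated background, and realized counts are
Poisson.  Particle numbers are drawn per realization from a Poisson law
(grand-canonical), which makes amplitude statistics match open-volume theory:
G(0) = 1/<N> with <N> = c * N_A * V_eff.

A trace is fully determined by its :class:`SimulationConfig`, including the
seed; identical configs give bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import propagate_and_detect

__all__ = [
    "AVOGADRO",
    "NM_PER_UM3",
    "DetectionVolume",
    "SpeciesSpec",
    "SimulationConfig",
    "IntensityTrace",
    "simulate_trace",
    "mean_count_rate",
    "expected_mean_rate",
    "sample_cell_values",
]

AVOGADRO = 6.02214076e23
#: molecules per um^3 at a concentration of 1 nM (1 nM ~ 0.602 molecules/fL)
NM_PER_UM3 = AVOGADRO * 1e-9 * 1e-15

# chunk of propagation steps held in memory at once; small enough to stay
# cache-friendly for a few thousand particles
_CHUNK_STEPS = 256


@dataclass(frozen=True)
class DetectionVolume:
    """Confocal observation volume, a 3D Gaussian with lateral 1/e^2 radius
    ``omega_xy`` (um) and axial elongation ``kappa = omega_z/omega_xy``."""

    omega_xy: float = 0.25
    kappa: float = 5.0

    def __post_init__(self):
        if self.omega_xy <= 0:
            raise ValueError("omega_xy must be positive")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1 (axially elongated volume)")

    @property
    def omega_z(self) -> float:
        return self.kappa * self.omega_xy

    @property
    def v_eff(self) -> float:
        """Effective volume pi^(3/2) * omega_xy^2 * omega_z in um^3 (= fL)."""
        return math.pi ** 1.5 * self.omega_xy**2 * self.omega_z


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing fluorescent species.

    brightness_G/R are mean detected count rates (Hz) for a particle at the
    volume center.  A dual-labeled (co-diffusing) species has both > 0.
    bleach_rate is a first-order photobleaching constant (1/s): each particle
    converts irreversibly to a dark state after an exponential lifetime with
    this rate, so the mean fluorescent number decays as N0 * exp(-k t).
    """

    name: str
    D: float                      # um^2/s
    concentration: float          # nM
    brightness_G: float = 0.0     # Hz per molecule at center
    brightness_R: float = 0.0
    bleach_rate: float = 0.0      # 1/s

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.brightness_G < 0 or self.brightness_R < 0:
            raise ValueError("brightness must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    volume: DetectionVolume = field(default_factory=DetectionVolume)
    species: tuple[SpeciesSpec, ...] = ()
    background_G: float = 0.0     # Hz
    background_R: float = 0.0
    duration: float = 120.0       # s
    base_bin: float = 2e-6        # s
    time_step: float = 1e-6       # s
    box_factor: float = 8.0       # box half-widths in units of (w_xy, w_xy, w_z)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.base_bin <= 0 or self.time_step <= 0:
            raise ValueError("base_bin and time_step must be positive")
        if self.base_bin < self.time_step:
            raise ValueError("base_bin must be >= time_step")
        spb = self.base_bin / self.time_step
        if abs(spb - round(spb)) > 1e-9 * spb:
            raise ValueError("base_bin must be an integer multiple of time_step")
        if self.box_factor < 5:
            raise ValueError("box_factor must be >= 5 so the detection profile "
                             "is negligible at the boundary")
        if self.background_G < 0 or self.background_R < 0:
            raise ValueError("background rates must be >= 0")
        visible = any(
            sp.concentration > 0 and (sp.brightness_G + sp.brightness_R) > 0
            for sp in self.species
        )
        if not visible and self.background_G == 0 and self.background_R == 0:
            raise ValueError("degenerate config: no visible species and no background")

    @property
    def half_widths(self) -> tuple[float, float, float]:
        w = self.volume
        return (self.box_factor * w.omega_xy,
                self.box_factor * w.omega_xy,
                self.box_factor * w.omega_z)

    @property
    def box_volume(self) -> float:
        hx, hy, hz = self.half_widths
        return 8.0 * hx * hy * hz

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.base_bin))

    @property
    def steps_per_bin(self) -> int:
        return int(round(self.base_bin / self.time_step))


@dataclass
class IntensityTrace:
    """Binned two-channel photon counts.

    Raw simulated traces hold integer counts; preprocessing (bleach
    detrending) may produce real-valued corrected counts in the same
    container.
    """

    counts_G: np.ndarray
    counts_R: np.ndarray
    bin_width: float
    metadata: dict = field(default_factory=dict)
    ground_truth: SimulationConfig | None = None

    def __post_init__(self):
        self.counts_G = np.asarray(self.counts_G, dtype=float)
        self.counts_R = np.asarray(self.counts_R, dtype=float)
        if self.counts_G.shape != self.counts_R.shape or self.counts_G.ndim != 1:
            raise ValueError("counts_G and counts_R must be 1-D arrays of equal length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.counts_G < 0) or np.any(self.counts_R < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts_G.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def counts(self, channel: str) -> np.ndarray:
        if channel == "G":
            return self.counts_G
        if channel == "R":
            return self.counts_R
        raise ValueError(f"unknown channel {channel!r}")

    def with_counts(self, channel: str, counts: np.ndarray) -> "IntensityTrace":
        kw = {"counts_G": self.counts_G, "counts_R": self.counts_R}
        kw["counts_" + channel] = np.asarray(counts, dtype=float)
        return IntensityTrace(bin_width=self.bin_width, metadata=dict(self.metadata),
                              ground_truth=self.ground_truth, **kw)


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))


def simulate_trace(config: SimulationConfig, metadata: dict | None = None) -> IntensityTrace:
    """Simulate a two-channel intensity trace for the given configuration.

    Each species is propagated independently; particles contribute their
    MDF value per step until their photobleaching lifetime expires, the
    per-bin MDF sum is scaled by channel brightness and the propagation
    time step to yield expected counts, and uncorrelated background is
    added.  Realized counts are Poisson draws.
    """
    rng = _rng(config.seed)
    n_bins = config.n_bins
    spb = config.steps_per_bin
    n_steps = n_bins * spb
    dt = config.time_step
    vol = config.volume
    hx, hy, hz = config.half_widths

    lam_G = np.full(n_bins, config.background_G * config.base_bin)
    lam_R = np.full(n_bins, config.background_R * config.base_bin)

    inv_wxy2 = 1.0 / vol.omega_xy**2
    inv_wz2 = 1.0 / vol.omega_z**2

    for sp in config.species:
        if sp.concentration <= 0 or (sp.brightness_G + sp.brightness_R) <= 0:
            continue
        n_mean = sp.concentration * NM_PER_UM3 * config.box_volume
        n_particles = int(rng.poisson(n_mean))
        if n_particles == 0:
            continue
        pos = np.empty((n_particles, 3))
        pos[:, 0] = rng.uniform(-hx, hx, n_particles)
        pos[:, 1] = rng.uniform(-hy, hy, n_particles)
        pos[:, 2] = rng.uniform(-hz, hz, n_particles)
        if sp.bleach_rate > 0:
            lifetimes = rng.exponential(1.0 / sp.bleach_rate, n_particles)
            death_step = np.minimum(np.ceil(lifetimes / dt), n_steps).astype(np.int64)
        else:
            death_step = np.full(n_particles, n_steps, dtype=np.int64)
        sigma = math.sqrt(2.0 * sp.D * dt)
        mdf_sum = np.zeros(n_bins)
        start = 0
        while start < n_steps:
            n = min(_CHUNK_STEPS, n_steps - start)
            uniforms = rng.random((n, n_particles, 3), dtype=np.float32)
            propagate_and_detect(pos, uniforms, sigma, spb, inv_wxy2, inv_wz2,
                                 hx, hy, hz, death_step, mdf_sum, start)
            start += n
        expected = mdf_sum * dt
        if sp.brightness_G > 0:
            lam_G += sp.brightness_G * expected
        if sp.brightness_R > 0:
            lam_R += sp.brightness_R * expected

    counts_G = rng.poisson(lam_G).astype(np.int64)
    counts_R = rng.poisson(lam_R).astype(np.int64)
    return IntensityTrace(counts_G=counts_G, counts_R=counts_R,
                          bin_width=config.base_bin,
                          metadata=dict(metadata or {}),
                          ground_truth=config)


def mean_count_rate(trace: IntensityTrace, channel: str) -> float:
    """Mean detected count rate (Hz): total counts / duration."""
    if trace.n_bins == 0:
        raise ValueError("empty trace")
    return float(trace.counts(channel).sum() / trace.duration)


def expected_mean_rate(config: SimulationConfig, channel: str) -> float:
    """Analytic expectation of the mean count rate (Hz) for a configuration.

    The spatial mean of the MDF over the periodic box is
    (pi/2)^(3/2) w_xy^2 w_z / V_box, and the time average of the bleaching
    decay over the acquisition is (1 - exp(-k T)) / (k T).
    """
    vol = config.volume
    mdf_integral = (math.pi / 2.0) ** 1.5 * vol.omega_xy**2 * vol.omega_z
    rate = config.background_G if channel == "G" else config.background_R
    for sp in config.species:
        q = sp.brightness_G if channel == "G" else sp.brightness_R
        if q <= 0 or sp.concentration <= 0:
            continue
        k = sp.bleach_rate
        decay_avg = 1.0 if k == 0 else (
            (1.0 - math.exp(-k * config.duration)) / (k * config.duration))
        rate += q * sp.concentration * NM_PER_UM3 * mdf_integral * decay_avg
    return rate


def sample_cell_values(median: float, spread: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell measurement values from a lognormal scatter model.

    Emulates the cell-to-cell spread of fitted quantities (D or c) around an
    ensemble median without propagating a full physical simulation per cell;
    used for repetition-heavy statistical studies (type-I error, power).
    ``spread`` is the characteristic half-width of the distribution around
    the median, mapped to the lognormal shape via
    sigma = ln(1 + spread/median), which keeps the median exact.
    """
    if median <= 0 or spread < 0 or n < 1:
        raise ValueError("median > 0, spread >= 0 and n >= 1 required")
    sigma = math.log1p(spread / median)
    return median * np.exp(sigma * rng.standard_normal(n))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
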