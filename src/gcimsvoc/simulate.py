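"""Synthetic GC-IMS cohorts with known ground truth.

The study's raw chromatograms are not publicly deposited, so every downstream
stage is exercised on simulated cohorts that carry the statistical structure
the analysis assumes.  A simulated map is

    RIP ridge  +  Σ analyte peaks  +  smooth baseline  +  white noise,

followed by an integer drift-bin jitter emulating instrumental drift.  The
RIP ridge is a narrow Gaussian in drift time, constant over retention.
Analyte peaks are separable 2-D Gaussians whose drift-time full width at half
maximum is ``drift_center / resolving_power`` with resolving power 75, the
figure quoted for the FlavourSpec drift tube.  The retention axis spans the
6-minute GC program (0–360 s).

Group structure: a subset of peaks is *discriminatory* — their amplitude is
multiplied by ``effect_size`` in the case group (the first group declared in
``group_n``).  Per-sample biological variation is log-normal with a given
coefficient of variation.  Everything is deterministic given the seed: the
peak layout derives from the cohort seed, and each sample draws from an
independent substream keyed by its position, so results do not depend on
iteration order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Chromatogram, Cohort, SampleRecord
from .preprocess import CropWindow

__all__ = [
    "PeakSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_chromatogram",
    "simulate_cohort",
    "default_crop_window",
    "default_background_window",
]


@dataclass(frozen=True)
class PeakSpec:
    """One analyte peak: centre, base amplitude and per-group multipliers."""

    ret_center: float          # s
    drift_center: float        # ms
    amplitude: float           # detector units
    group_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if any(m <= 0 for m in self.group_multipliers.values()):
            raise ValueError("group multipliers must be > 0")

    def multiplier(self, group: str) -> float:
        return self.group_multipliers.get(group, 1.0)


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the study's scale: 13 cases vs 7 refractory cases vs
    10 controls, a 6-min GC run, a 5–15 ms drift window, 30 analyte peaks of
    which 5 discriminate, and a four-fold multiplicative intensity shift on
    the discriminatory peaks in the case group.
    """

    group_n: dict = field(
        default_factory=lambda: {"CD": 13, "RCD": 7, "HC": 10})
    n_ret: int = 120
    n_drift: int = 110
    ret_span: tuple = (0.0, 360.0)      # s, 6-min GC program
    drift_span: tuple = (5.0, 15.0)     # ms
    n_peaks: int = 30
    n_discriminatory: int = 5
    effect_size: float = 4.0            # case-group multiplier
    resolving_power: float = 75.0       # drift FWHM = center / power
    ret_sigma_s: float = 5.0            # GC peak width (sd, s)
    rip_drift_ms: float = 7.0
    rip_amplitude: float = 500.0
    amplitude_range: tuple = (50.0, 150.0)   # analyte base amplitudes
    peak_region: tuple = (30.0, 330.0, 7.8, 13.0)  # ret×drift placement box
    noise_sd: float = 3.0
    baseline_amplitude: float = 10.0
    jitter_max_bins: int = 2
    biological_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discriminatory > self.n_peaks:
            raise ValueError("n_discriminatory must be <= n_peaks")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if any(n < 0 for n in self.group_n.values()):
            raise ValueError("group sizes must be >= 0")

    @property
    def case_group(self) -> str:
        return next(iter(self.group_n))

    def retention_axis(self) -> np.ndarray:
        return np.linspace(*self.ret_span, self.n_ret)

    def drift_axis(self) -> np.ndarray:
        return np.linspace(*self.drift_span, self.n_drift)


@dataclass
class GroundTruth:
    """What the generator planted: the recovery targets for the pipeline."""

    discriminatory_peaks: list           # PeakSpec
    discriminatory_pixels: list          # (ret_idx, drift_idx) on the grid
    jitter_bins: dict                    # sample_id -> applied drift shift
    peak_amplitudes: dict                # sample_id -> per-peak amplitude

    def to_json(self) -> str:
        payload = {
            "discriminatory_peaks": [
                dataclasses.asdict(p) for p in self.discriminatory_peaks],
            "discriminatory_pixels": [list(map(int, px))
                                      for px in self.discriminatory_pixels],
            "jitter_bins": {k: int(v) for k, v in self.jitter_bins.items()},
            "peak_amplitudes": {k: [float(a) for a in v]
                                for k, v in self.peak_amplitudes.items()},
        }
        return json.dumps(payload, indent=1)


def default_crop_window(config: SimulationConfig) -> CropWindow:
    """Analyte region for this generator, keeping the RIP ridge inside.

    The RIP is the registration landmark for realignment, so the window
    starts 0.5 ms below it on the drift axis and extends past the analyte
    placement box.
    """
    return CropWindow(ret_min=20.0, ret_max=350.0,
                      drift_min=config.rip_drift_ms - 0.5, drift_max=14.0)


def default_background_window(config: SimulationConfig) -> CropWindow:
    """A strip with no RIP and no analyte peaks, for auto-thresholding.

    Lies inside :func:`default_crop_window` because thresholding runs on the
    cropped map.
    """
    return CropWindow(ret_min=20.0, ret_max=350.0,
                      drift_min=13.4, drift_max=14.0)


def _layout_peaks(config: SimulationConfig) -> list:
    """Draw the cohort-wide peak layout from the config seed."""
    rng = np.random.default_rng([int(config.seed), 0xA11])
    r0, r1, d0, d1 = config.peak_region
    rets = rng.uniform(r0, r1, config.n_peaks)
    drifts = rng.uniform(d0, d1, config.n_peaks)
    amps = rng.uniform(*config.amplitude_range, config.n_peaks)
    disc = rng.choice(config.n_peaks, size=config.n_discriminatory,
                      replace=False)
    case = config.case_group
    peaks = []
    for i in range(config.n_peaks):
        mult = {case: config.effect_size} if i in disc else {}
        peaks.append(PeakSpec(ret_center=float(rets[i]),
                              drift_center=float(drifts[i]),
                              amplitude=float(amps[i]),
                              group_multipliers=mult))
    return peaks


def _peak_field(peaks, ret_axis, drift_axis, amplitudes, group,
                config) -> np.ndarray:
    """Sum of separable 2-D Gaussians (exploits separability for speed)."""
    field_ = np.zeros((ret_axis.size, drift_axis.size))
    fwhm_to_sd = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for peak, amp in zip(peaks, amplitudes):
        drift_sd = (peak.drift_center / config.resolving_power) * fwhm_to_sd
        ret_prof = np.exp(-0.5 * ((ret_axis - peak.ret_center)
                                  / config.ret_sigma_s) ** 2)
        drift_prof = np.exp(-0.5 * ((drift_axis - peak.drift_center)
                                    / drift_sd) ** 2)
        field_ += (amp * peak.multiplier(group)) * np.outer(ret_prof,
                                                            drift_prof)
    return field_


def simulate_chromatogram(config: SimulationConfig, group: str,
                          rng: np.random.Generator,
                          peaks: list | None = None,
                          sample_id: str = "sample"):
    """Simulate one chromatogram; returns ``(Chromatogram, truth_dict)``.

    ``peaks`` defaults to the layout derived from ``config.seed`` so that
    stand-alone calls are consistent with :func:`simulate_cohort`.
    Deterministic given ``rng`` state.
    """
    if peaks is None:
        peaks = _layout_peaks(config)
    ret_axis = config.retention_axis()
    drift_axis = config.drift_axis()
    r0, r1 = config.ret_span
    d0, d1 = config.drift_span
    for p in peaks:
        if not (r0 <= p.ret_center <= r1 and d0 <= p.drift_center <= d1):
            raise ValueError(
                f"peak center ({p.ret_center} s, {p.drift_center} ms) "
                "outside the simulated grid")

    # per-sample lognormal amplitude variation (unit mean)
    if config.biological_cv > 0:
        sigma = np.sqrt(np.log1p(config.biological_cv ** 2))
        factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                size=len(peaks))
    else:
        factors = np.ones(len(peaks))
    amplitudes = np.array([p.amplitude for p in peaks]) * factors

    fwhm_to_sd = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rip_sd = (config.rip_drift_ms / config.resolving_power) * fwhm_to_sd
    rip = config.rip_amplitude * np.exp(
        -0.5 * ((drift_axis - config.rip_drift_ms) / rip_sd) ** 2)
    intensity = np.broadcast_to(rip, (config.n_ret, config.n_drift)).copy()

    if peaks:
        intensity += _peak_field(peaks, ret_axis, drift_axis, amplitudes,
                                 group, config)

    if config.baseline_amplitude > 0:
        ph_r, ph_d = rng.uniform(0, 2 * np.pi, 2)
        rr = np.linspace(0, 2 * np.pi, config.n_ret)
        dd = np.linspace(0, 2 * np.pi, config.n_drift)
        base = (config.baseline_amplitude
                * np.outer(0.5 + 0.5 * np.sin(rr + ph_r),
                           0.5 + 0.5 * np.cos(dd + ph_d)))
        intensity += base

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, config.noise_sd, intensity.shape)

    jitter = int(rng.integers(-config.jitter_max_bins,
                              config.jitter_max_bins + 1)) \
        if config.jitter_max_bins > 0 else 0
    if jitter:
        shifted = np.zeros_like(intensity)
        if jitter > 0:
            shifted[:, jitter:] = intensity[:, :-jitter]
        else:
            shifted[:, :jitter] = intensity[:, -jitter:]
        intensity = shifted

    chrom = Chromatogram(sample_id=sample_id, intensity=intensity,
                         retention_axis=ret_axis, drift_axis=drift_axis)
    truth = {"jitter_bins": jitter, "peak_amplitudes": amplitudes}
    return chrom, truth


def _nearest_bin(axis: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(axis - value)))


def simulate_cohort(config: SimulationConfig):
    """Simulate a full cohort; returns ``(Cohort, GroundTruth)``.

    Sample ids are ``<group>-<k>``; each sample uses an RNG substream keyed
    by ``(seed, sample index)`` so the cohort is reproducible bitwise and
    independent of generation order.
    """
    for g, n in config.group_n.items():
        if n == 0:
            raise ValueError(f"declared group {g!r} has zero samples")
    peaks = _layout_peaks(config)
    disc = [p for p in peaks if p.group_multipliers]
    ret_axis = config.retention_axis()
    drift_axis = config.drift_axis()
    pixels = [(_nearest_bin(ret_axis, p.ret_center),
               _nearest_bin(drift_axis, p.drift_center)) for p in disc]

    records, chroms = [], {}
    jitters, amps = {}, {}
    idx = 0
    for group, n in config.group_n.items():
        for k in range(n):
            sid = f"{group}-{k + 1:02d}"
            rng = np.random.default_rng([int(config.seed), 1, idx])
            chrom, truth = simulate_chromatogram(
                config, group, rng, peaks=peaks, sample_id=sid)
            records.append(SampleRecord(sample_id=sid, group=group,
                                        covariates={}))
            chroms[sid] = chrom
            jitters[sid] = truth["jitter_bins"]
            amps[sid] = truth["peak_amplitudes"]
            idx += 1

    cohort = Cohort(records=records, chromatograms=chroms)
    truth = GroundTruth(discriminatory_peaks=disc,
                        discriminatory_pixels=pixels,
                        jitter_bins=jitters,
                        peak_amplitudes=amps)
    return cohort, truth
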