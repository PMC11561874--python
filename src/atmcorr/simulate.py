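"""Synthetic FTIR scene generator.

Each simulated scan is the sum of a fixed analyte spectrum and fixed
interferent basis spectra, the latter multiplied by per-scan coefficients
that model the time-varying concentration of each vapor in the beam path.
The whole trace is convolved with a Gaussian instrument lineshape, then a
per-scan baseline offset (drift) and white noise are added.

Interferent bases are Lorentzian line combs (pressure-broadened rotational
lines); analyte bands are Gaussians (condensed phase). The exact closed-form
scaling factor for each sequential pair is recorded in the scene truth, so
every stage of the correction pipeline can be tested against ground truth
without instrument data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .correction import correct_series
from .errors import ConfigError
from .evaluation import DEFAULT_REFERENCE, rsd_profile
from .spectra import InterferentSpec, Region, Spectrum, SpectrumSeries

__all__ = [
    "LineComb",
    "SceneConfig",
    "SceneTruth",
    "render_comb",
    "render_analyte",
    "simulate_series",
    "resolution_sweep",
    "default_water_comb",
    "default_co2_comb",
    "alternating_trajectory",
    "headline_rsd_scene",
    "resolution_scene",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LineComb:
    """Set of Lorentzian lines standing in for vapor rotational fine structure.

    ``window``, when set, multiplies the rendered profile by a raised-cosine
    taper that is exactly zero at and outside the window bounds -- a stand-in
    for a vibrational band envelope with compact support, which also makes
    noiseless exact-recovery tests well posed (the interferent then vanishes
    at the correction-region boundaries instead of leaking Lorentzian wings
    into the splice joins).
    """

    centers: np.ndarray
    intensities: np.ndarray
    fwhm: float
    window: tuple[float, float] | None = None
    window_taper: float = 0.15  # fraction of the window ramped at each edge

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        if self.centers.size != self.intensities.size:
            raise ConfigError("centers and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise ConfigError("line intensities must be >= 0")
        if self.fwhm <= 0:
            raise ConfigError("line FWHM must be > 0")


@dataclass
class SceneConfig:
    """Full description of a synthetic sequential-measurement scene.

    ``interferents`` pairs each :class:`InterferentSpec` with its line comb
    and a coefficient trajectory c(t), one value per scan. All trajectories
    must have the same length (the scan count, >= 2).
    """

    axis: tuple[float, float, float]  # (lo, hi, spacing) in cm^-1
    analyte_bands: list[tuple[float, float, float]]  # (center, height, fwhm)
    interferents: list[tuple[InterferentSpec, LineComb, np.ndarray]]
    analyte_offset: float = 0.0  # flat solvent/baseline absorbance (AU)
    noise_sd: float = 0.0
    drift: tuple[float, float] = (0.0, 0.0)  # (slope per scan, curvature)
    resolution_fwhm: float = 0.0  # 0 disables instrument convolution
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, spacing = self.axis
        if spacing <= 0 or hi <= lo:
            raise ConfigError(f"invalid axis {self.axis}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.interferents:
            raise ConfigError("scene needs at least one interferent")
        lengths = {len(np.atleast_1d(c)) for _, _, c in self.interferents}
        if len(lengths) != 1:
            raise ConfigError(
                f"coefficient trajectories have differing lengths {sorted(lengths)}"
            )
        (self.n_scans,) = lengths
        if self.n_scans < 2:
            raise ConfigError("trajectories must cover >= 2 scans")
        for spec, comb, _ in self.interferents:
            regions = [spec.correct_region]
            if spec.gamma_region is not None:
                regions.append(spec.gamma_region)
            outside = [
                c for c in comb.centers
                if not any(r.lo <= c <= r.hi for r in regions)
            ]
            if outside:
                # the vapor absorbs where it absorbs; lines outside the
                # configured regions simply will not be corrected
                warnings.warn(
                    f"{spec.name}: {len(outside)} line center(s) outside the "
                    "configured correction/estimation regions will be left "
                    "uncorrected",
                    stacklevel=2,
                )

    def make_axis(self) -> np.ndarray:
        lo, hi, spacing = self.axis
        n = int(round((hi - lo) / spacing)) + 1
        return lo + spacing * np.arange(n)


@dataclass
class SceneTruth:
    """Ground truth for a simulated scene."""

    analyte: Spectrum
    interferent_bases: dict[str, np.ndarray]
    coefficients: dict[str, np.ndarray]
    gamma_true: dict[tuple[str, int], float] = field(default_factory=dict)


def render_comb(comb: LineComb, axis: np.ndarray) -> np.ndarray:
    """Sum of Lorentzian lines; an isolated line peaks at its intensity."""
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    hw2 = (comb.fwhm / 2.0) ** 2
    for c, a in zip(comb.centers, comb.intensities):
        out += a * hw2 / ((axis - c) ** 2 + hw2)
    if comb.window is not None:
        out *= _cosine_window(axis, comb.window, comb.window_taper)
    return out


def _cosine_window(axis: np.ndarray, window: tuple[float, float],
                   taper: float) -> np.ndarray:
    lo, hi = window
    ramp = taper * (hi - lo)
    w = np.zeros_like(axis)
    inside = (axis > lo) & (axis < hi)
    w[inside] = 1.0
    left = inside & (axis < lo + ramp)
    w[left] = 0.5 * (1.0 - np.cos(np.pi * (axis[left] - lo) / ramp))
    right = inside & (axis > hi - ramp)
    w[right] = 0.5 * (1.0 - np.cos(np.pi * (hi - axis[right]) / ramp))
    return w


def render_analyte(
    bands: list[tuple[float, float, float]], axis: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian bands (center, height, fwhm)."""
    axis = np.asarray(axis, dtype=float)
    spacing = float(axis[1] - axis[0]) if axis.size > 1 else 0.0
    out = np.zeros_like(axis)
    for center, height, fwhm in bands:
        if spacing and fwhm < 2.0 * spacing:
            warnings.warn(
                f"analyte band at {center} cm^-1 (fwhm {fwhm}) is narrower than "
                f"2x the axis spacing ({spacing}); it will be under-resolved",
                stacklevel=2,
            )
        out += height * np.exp(-4.0 * np.log(2.0) * (axis - center) ** 2 / fwhm**2)
    return out


def _instrument_blur(y: np.ndarray, fwhm: float, spacing: float) -> np.ndarray:
    if fwhm <= 0:
        return y
    sigma_pts = fwhm * _FWHM_TO_SIGMA / spacing
    return gaussian_filter1d(y, sigma_pts, mode="nearest")


def simulate_series(cfg: SceneConfig) -> tuple[SpectrumSeries, SceneTruth]:
    """Render the scene's sequential scans and the matching ground truth.

    The truth's analyte and interferent bases are the *instrument-convolved*
    traces -- convolution is linear, so they are exactly what a perfect
    correction recovers. gamma_true[(name, k)] is the closed-form scaling
    factor c(t_k) / (c(t_k) - c(t_{k+1})) for the "next"-pairing of scan k.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.make_axis()
    spacing = cfg.axis[2]

    analyte = cfg.analyte_offset + _instrument_blur(
        render_analyte(cfg.analyte_bands, axis), cfg.resolution_fwhm, spacing
    )
    bases: dict[str, np.ndarray] = {}
    coeffs: dict[str, np.ndarray] = {}
    for spec, comb, traj in cfg.interferents:
        if spec.name in bases:
            raise ConfigError(f"duplicate interferent name {spec.name!r}")
        bases[spec.name] = _instrument_blur(render_comb(comb, axis),
                                            cfg.resolution_fwhm, spacing)
        coeffs[spec.name] = np.atleast_1d(np.asarray(traj, dtype=float)).copy()

    slope, curvature = cfg.drift
    spectra = []
    for k in range(cfg.n_scans):
        y = analyte.copy()
        for name, basis in bases.items():
            y = y + coeffs[name][k] * basis
        y = y + slope * k + curvature * k * k
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd, size=axis.size)
        spectra.append(
            Spectrum(axis.copy(), y, timestamp=float(k),
                     resolution=cfg.resolution_fwhm or None, label=f"scan{k:03d}")
        )
    series = SpectrumSeries(spectra, sample_id=f"scene-seed{cfg.seed}")

    truth = SceneTruth(
        analyte=Spectrum(axis.copy(), analyte, label="analyte-truth"),
        interferent_bases=bases,
        coefficients=coeffs,
    )
    for name, c in coeffs.items():
        for k in range(cfg.n_scans - 1):
            denom = c[k] - c[k + 1]
            if denom != 0.0:
                truth.gamma_true[(name, k)] = float(c[k] / denom)
    return series, truth


def default_water_comb(seed: int = 0, lo: float = 1300.0, hi: float = 1950.0,
                       n_lines: int = 40, fwhm: float = 4.0) -> LineComb:
    """Seeded stand-in for the water-bend rotational comb (fixture convention)."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(lo, hi, n_lines)
    intensities = rng.uniform(0.2, 1.0, size=n_lines)
    return LineComb(centers, intensities, fwhm)


def default_co2_comb(seed: int = 0, lo: float = 2300.0, hi: float = 2380.0,
                     n_lines: int = 25, fwhm: float = 3.0) -> LineComb:
    """Seeded stand-in for the CO2 asymmetric-stretch band (fixture convention)."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(lo, hi, n_lines)
    intensities = rng.uniform(0.3, 1.0, size=n_lines)
    return LineComb(centers, intensities, fwhm)


def alternating_trajectory(rng: np.random.Generator, n_scans: int,
                           amplitude: float) -> np.ndarray:
    """Coefficient trajectory fluctuating around zero with alternating sign.

    With a fresh background the static interferent level is removed, so the
    residual coefficient fluctuates around 0. Alternating sign with magnitude
    uniform in [0.5, 1.5] x amplitude keeps consecutive differences bounded
    away from zero, i.e. the pairwise scaling factors stay well conditioned.
    """
    signs = (-1.0) ** np.arange(n_scans)
    return amplitude * signs * rng.uniform(0.5, 1.5, size=n_scans)


def headline_rsd_scene(
    seed: int,
    n_scans: int = 30,
    noise_sd: float = 0.002,
    interferent_to_noise: float = 10.0,
    spacing: float = 4.0,
) -> SceneConfig:
    """Replicate series with a fluctuating water comb for the RSD comparison.

    The coefficient amplitude is calibrated so the median per-point standard
    deviation contributed by the interferent inside its region equals
    ``interferent_to_noise`` times the white-noise sigma. Axis spans both the
    water target region and the feature-free 4800-5000 cm^-1 reference.
    """
    rng = np.random.default_rng(seed)
    comb = LineComb(
        centers=np.arange(1260.0, 2000.0, 9.0),
        intensities=rng.uniform(0.3, 1.0, size=np.arange(1260.0, 2000.0, 9.0).size),
        fwhm=5.0,
        window=(1230.0, 2040.0),
    )
    spec = InterferentSpec("H2O-bend", Region(1205.0, 2072.0))
    axis_cfg = (1000.0, 5050.0, spacing)
    # calibrate amplitude: median |basis| inside the comb window
    probe = np.arange(1230.0, 2040.0, spacing)
    med_w = float(np.median(render_comb(comb, probe)))
    traj_unit = alternating_trajectory(rng, n_scans, 1.0)
    amp = interferent_to_noise * noise_sd / (med_w * float(np.std(traj_unit)))
    return SceneConfig(
        axis=axis_cfg,
        analyte_bands=[(1100.0, 0.3, 40.0), (2900.0, 0.4, 60.0)],
        analyte_offset=0.1,
        interferents=[(spec, comb, amp * traj_unit)],
        noise_sd=noise_sd,
        drift=(0.3 * noise_sd, 0.0),
        seed=seed,
    )


def resolution_scene(seed: int, n_scans: int = 9, noise_sd: float = 0.003) -> SceneConfig:
    """Base scene for the instrument-width sweep: a water comb whose ~2 cm^-1
    lines (16 cm^-1 apart) stay resolved up to ~8 cm^-1 instrument width and
    merge at 16 cm^-1."""
    rng = np.random.default_rng(seed)
    centers = np.arange(1270.0, 2000.0, 16.0)
    comb = LineComb(centers, rng.uniform(0.3, 1.0, size=centers.size), 2.5,
                    window=(1230.0, 2040.0))
    spec = InterferentSpec("H2O-bend", Region(1205.0, 2072.0))
    return SceneConfig(
        axis=(1000.0, 5050.0, 2.0),  # spacing overridden per width by the sweep
        analyte_bands=[(1100.0, 0.3, 40.0)],
        analyte_offset=0.1,
        interferents=[(spec, comb,
                       alternating_trajectory(rng, n_scans, 30.0 * noise_sd))],
        noise_sd=noise_sd,
        drift=(0.3 * noise_sd, 0.0),
        seed=seed,
    )


def resolution_sweep(
    cfg: SceneConfig,
    fwhms: list[float],
    target: Region | None = None,
    reference: Region = DEFAULT_REFERENCE,
    pairing: str = "next",
) -> dict[float, dict]:
    """Rerun the scene at several instrument widths and compare RSD before
    and after correction.

    For each width the axis spacing is set to FWHM / 2 and the instrument
    convolution to that FWHM; the series is corrected and the RSD of the
    (first interferent's) correction region summarized for both series.
    """
    out: dict[float, dict] = {}
    interferent_specs = [spec for spec, _, _ in cfg.interferents]
    tgt = target if target is not None else interferent_specs[0].correct_region
    for fwhm in fwhms:
        lo, hi, _ = cfg.axis
        sub = SceneConfig(
            axis=(lo, hi, fwhm / 2.0),
            analyte_bands=cfg.analyte_bands,
            interferents=cfg.interferents,
            analyte_offset=cfg.analyte_offset,
            noise_sd=cfg.noise_sd,
            drift=cfg.drift,
            resolution_fwhm=fwhm,
            seed=cfg.seed,
        )
        series, truth = simulate_series(sub)
        corrected, results = correct_series(series, interferent_specs, pairing=pairing)
        # drop the unpaired scan from the raw series so both RSDs use the
        # same replicate count
        raw = SpectrumSeries(
            series.spectra[:-1] if pairing == "next" else series.spectra[1:],
            sample_id=series.sample_id,
        )
        rsd_unc = rsd_profile(raw, target=tgt, reference=reference)
        rsd_cor = rsd_profile(corrected, target=tgt, reference=reference)
        out[fwhm] = {
            "uncorrected": series,
            "corrected": corrected,
            "truth": truth,
            "results": results,
            "rsd_uncorrected": rsd_unc,
            "rsd_corrected": rsd_cor,
            "rsd_mean_uncorrected": rsd_unc.mean,
            "rsd_mean_corrected": rsd_cor.mean,
        }
    return out
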