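"""Two-spectrum atmospheric correction.

Given two sequential spectra of the same sample, the change in atmospheric
absorption between them is isolated as a difference spectrum ``D`` inside a
configured interferent region. A scaling factor ``gamma`` is then chosen so
that subtracting ``gamma * D`` from the first spectrum minimizes the
point-to-point length of the segment -- the length is minimal when the sharp
rotational fine structure of the vapor has been cancelled. The corrected
segment is spliced back over the original region with a linear ramp that
matches the absorbances at both ends.

The objective L(gamma) is convex: each summand is the Euclidean norm of an
affine function of gamma, so bounded scalar minimization finds the unique
minimizer whenever ``D`` is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import (
    DegenerateDifferenceError,
    PairingError,
    ShapeError,
    TooShortError,
)
from .spectra import (
    InterferentSpec,
    Region,
    Spectrum,
    SpectrumSeries,
    assert_common_axis_list,
    slice_region,
)

__all__ = [
    "DifferenceSpectrum",
    "GammaCurve",
    "CorrectionResult",
    "difference_spectrum",
    "point_to_point_length",
    "length_of_corrected",
    "optimize_gamma",
    "apply_correction",
    "splice",
    "correct_pair",
    "correct_series",
    "DEFAULT_BOUNDS",
    "DEFAULT_TOL",
    "DEGENERATE_FLOOR",
]

DEFAULT_BOUNDS: tuple[float, float] = (-50.0, 50.0)
DEFAULT_TOL: float = 1e-8
#: below this max|D| (AU) the pair carries no usable atmospheric change
DEGENERATE_FLOOR: float = 1e-6


@dataclass
class DifferenceSpectrum:
    """Point-by-point difference of two sequential spectra over one region."""

    values: np.ndarray
    region: Region
    index_range: tuple[int, int]
    pair: tuple[float, float]  # (timestamp1, timestamp2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 3:
            raise TooShortError("difference spectrum needs >= 3 points")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("difference spectrum contains non-finite values")


@dataclass
class GammaCurve:
    """Sampled L(gamma) diagnostics plus the optimum found."""

    gammas: np.ndarray
    lengths: np.ndarray
    gamma_opt: float
    length_opt: float
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    at_bound: bool = False


@dataclass
class CorrectionResult:
    """Output of correcting one spectrum against its sequential partner."""

    corrected: Spectrum
    per_interferent: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def point_to_point_length(y: np.ndarray, dx: float = 1.0) -> float:
    """Sum of Euclidean segment lengths between consecutive samples.

    Both coordinates are treated as unitless; ``dx`` is the constant x
    spacing (sample index spacing by default). A flat trace of n points has
    the minimum possible length (n-1)*dx; any sharp structure increases it.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise TooShortError("need >= 2 points for a point-to-point length")
    if dx <= 0:
        raise ShapeError(f"dx must be positive, got {dx}")
    return float(np.sum(np.hypot(dx, np.diff(y))))


def difference_spectrum(s1: Spectrum, s2: Spectrum, r: Region) -> DifferenceSpectrum:
    """D = S(t1) - S(t2) restricted to region ``r``."""
    assert_common_axis_list([s1, s2])
    (i_lo, i_hi), seg1 = slice_region(s1, r)
    d = seg1.absorbance - s2.absorbance[i_lo : i_hi + 1]
    return DifferenceSpectrum(d, r, (i_lo, i_hi), (s1.timestamp, s2.timestamp))


def length_of_corrected(
    s1_seg: np.ndarray, D: DifferenceSpectrum, gamma: float, dx: float = 1.0
) -> float:
    """Point-to-point length of ``s1_seg - gamma * D.values``."""
    s1_seg = np.asarray(s1_seg, dtype=float)
    if s1_seg.size != D.values.size:
        raise ShapeError(
            f"segment length {s1_seg.size} != difference length {D.values.size}"
        )
    return point_to_point_length(s1_seg - gamma * D.values, dx)


def optimize_gamma(
    s1_seg: np.ndarray,
    D: DifferenceSpectrum,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = DEFAULT_TOL,
    dx: float = 1.0,
    noise_floor: float | None = None,
    curve_points: int = 41,
) -> GammaCurve:
    """Find the scaling factor minimizing the corrected segment's length.

    Raises DegenerateDifferenceError when max|D| is below the noise floor
    (default ``max(1e-6, 3 * noise_floor)``): the scaling factor is then
    unbounded and no correction should be applied.
    """
    s1_seg = np.asarray(s1_seg, dtype=float)
    if s1_seg.size != D.values.size:
        raise ShapeError(
            f"segment length {s1_seg.size} != difference length {D.values.size}"
        )
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ShapeError(f"bounds must be finite with lo < hi, got {bounds}")

    floor = DEGENERATE_FLOOR
    if noise_floor is not None:
        floor = max(floor, 3.0 * noise_floor)
    if np.max(np.abs(D.values)) < floor:
        raise DegenerateDifferenceError(
            f"max|D| = {np.max(np.abs(D.values)):.3g} AU is below the noise "
            f"floor {floor:.3g}; advise gamma = 0 (no correction)"
        )

    diffs = np.diff(s1_seg)
    ddiffs = np.diff(D.values)

    def objective(g: float) -> float:
        return float(np.sum(np.hypot(dx, diffs - g * ddiffs)))

    def gradient(g: float) -> float:
        r = diffs - g * ddiffs
        return float(np.sum(-ddiffs * r / np.hypot(dx, r)))

    # L is convex, so its derivative is nondecreasing: locate the minimizer
    # as the derivative's root (machine precision), falling back to bounded
    # scalar minimization only in the flat/degenerate case.
    g_lo, g_hi = gradient(lo), gradient(hi)
    if g_lo >= 0.0:
        gamma_opt = lo
    elif g_hi <= 0.0:
        gamma_opt = hi
    else:
        try:
            gamma_opt = float(brentq(gradient, lo, hi, xtol=min(tol, 1e-12)))
        except ValueError:
            gamma_opt = float(
                minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                options={"xatol": tol}).x
            )
    length_opt = objective(gamma_opt)

    grid = np.linspace(lo, hi, max(curve_points, 41))
    lengths = np.array([objective(g) for g in grid])
    i_best = int(np.argmin(lengths))
    if lengths[i_best] < length_opt:  # never report worse than the sampled curve
        gamma_opt, length_opt = float(grid[i_best]), float(lengths[i_best])
    at_bound = min(gamma_opt - lo, hi - gamma_opt) <= max(tol, 1e-12)
    return GammaCurve(grid, lengths, gamma_opt, length_opt, (lo, hi), at_bound)


def apply_correction(s1: Spectrum, D: DifferenceSpectrum, gamma: float) -> Spectrum:
    """Minimized-length segment: s1 restricted to D's region minus gamma*D."""
    (i_lo, i_hi), seg = slice_region(s1, D.region)
    if (i_lo, i_hi) != D.index_range:
        raise ShapeError(
            f"difference spectrum indexed {D.index_range} does not match "
            f"region slice {(i_lo, i_hi)} on this axis"
        )
    seg.absorbance = seg.absorbance - gamma * D.values
    seg.metadata["gamma"] = gamma
    return seg


def splice(s1: Spectrum, s_m: Spectrum, r: Region) -> Spectrum:
    """Overwrite region ``r`` of ``s1`` with segment ``s_m``, blending a
    linear ramp so both joins are continuous with the surrounding spectrum.

    The ramp interpolates the endpoint mismatches against the axis points
    immediately *outside* the region; if the region abuts an axis end, a
    constant offset matching the single interior join is used.
    """
    i_lo, i_hi = _seg_range(s1, s_m, r)
    n = i_hi - i_lo + 1
    out = s1.copy()
    seg = s_m.absorbance

    left_delta = s1.absorbance[i_lo - 1] - seg[0] if i_lo > 0 else None
    right_delta = s1.absorbance[i_hi + 1] - seg[-1] if i_hi < len(s1) - 1 else None
    if left_delta is None and right_delta is None:
        ramp = np.zeros(n)
    elif left_delta is None:
        ramp = np.full(n, right_delta)
    elif right_delta is None:
        ramp = np.full(n, left_delta)
    else:
        ramp = np.linspace(left_delta, right_delta, n)
    out.absorbance[i_lo : i_hi + 1] = seg + ramp
    return out


def _seg_range(s1: Spectrum, s_m: Spectrum, r: Region) -> tuple[int, int]:
    (i_lo, i_hi), _ = slice_region(s1, r)
    if s_m.wavenumbers.size != i_hi - i_lo + 1 or not np.array_equal(
        s_m.wavenumbers, s1.wavenumbers[i_lo : i_hi + 1]
    ):
        raise ShapeError("segment does not span the region's index range on this axis")
    return i_lo, i_hi


def correct_pair(
    s1: Spectrum,
    s2: Spectrum,
    interferents: list[InterferentSpec],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = DEFAULT_TOL,
    noise_floor: float | None = None,
) -> CorrectionResult:
    """Correct ``s1`` using its sequential partner ``s2``.

    Interferents are processed in configuration order, each operating on the
    output of the previous one. For each interferent the scaling factor is
    estimated in ``gamma_region`` when configured (regions clean of sharp
    analyte peaks) and *transferred* to ``correct_region``; otherwise both
    steps use ``correct_region``. A degenerate difference (no atmospheric
    change between the pair) yields gamma = 0 and a warning, never a failure.
    """
    assert_common_axis_list([s1, s2])
    axis = s1.wavenumbers
    current = s1.copy()
    result = CorrectionResult(corrected=current)
    for spec in interferents:
        gr = spec.gamma_region_used
        uncovered = [
            r for r in {(gr.lo, gr.hi), (spec.correct_region.lo, spec.correct_region.hi)}
            if r[1] < axis[0] or r[0] > axis[-1]
        ]
        if uncovered:
            # regions outside the measured span are simply not present in
            # this acquisition (common with the full default config)
            result.warnings.append(
                f"{spec.name}: region(s) {sorted(uncovered)} outside the "
                f"measured axis ({axis[0]:g}-{axis[-1]:g} cm^-1); skipped"
            )
            continue
        d_gamma = difference_spectrum(current, s2, gr)
        (g_lo, g_hi), _ = slice_region(current, gr)
        seg_gamma = current.absorbance[g_lo : g_hi + 1]
        try:
            curve = optimize_gamma(
                seg_gamma, d_gamma, bounds=bounds, tol=tol, noise_floor=noise_floor
            )
            gamma = curve.gamma_opt
            if curve.at_bound:
                result.warnings.append(
                    f"{spec.name}: gamma = {gamma:.4g} is at the search bound "
                    f"{curve.bounds}; estimate unreliable"
                )
        except DegenerateDifferenceError:
            gamma = 0.0
            curve = None
            result.warnings.append(
                f"{spec.name}: difference spectrum below noise floor; "
                "no correction applied (gamma = 0)"
            )
        d_corr = difference_spectrum(current, s2, spec.correct_region)
        if gamma != 0.0:
            s_m = apply_correction(current, d_corr, gamma)
            current = splice(current, s_m, spec.correct_region)
        result.per_interferent[spec.name] = {
            "gamma": gamma,
            "difference": d_corr,
            "curve": curve,
            "gamma_region_used": gr,
        }
    result.corrected = current
    result.corrected.metadata["corrected"] = True
    return result


def correct_series(
    series: SpectrumSeries,
    interferents: list[InterferentSpec],
    pairing: str = "next",
    **kwargs,
) -> tuple[SpectrumSeries, list[CorrectionResult]]:
    """Correct every spectrum of a series against a sequential partner.

    Under the default ``"next"`` policy spectrum k is corrected with spectrum
    k+1 and the final spectrum, having no successor, is dropped (n-1
    outputs). Under ``"previous"`` the first spectrum is dropped instead.
    """
    n = len(series)
    if n < 2:
        raise PairingError(f"need >= 2 spectra to form pairs, got {n}")
    if pairing not in ("next", "previous"):
        raise PairingError(f"unknown pairing policy {pairing!r}")
    pairs = (
        [(k, k + 1) for k in range(n - 1)]
        if pairing == "next"
        else [(k, k - 1) for k in range(1, n)]
    )
    results = []
    corrected = []
    for i, j in pairs:
        res = correct_pair(series[i], series[j], interferents, **kwargs)
        results.append(res)
        corrected.append(res.corrected)
    return SpectrumSeries(corrected, sample_id=series.sample_id), results
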