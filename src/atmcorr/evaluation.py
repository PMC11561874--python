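"""Relative-standard-deviation (RSD) efficacy metric.

Across replicate spectra of one sample, the per-wavenumber standard
deviation inside an interferent region is normalized by the mean standard
deviation of a reference region devoid of spectral features. The reference
captures the baseline variability from noise and slow instrumental drift,
so an RSD near 1 means only noise/drift remains; fluctuating atmospheric
absorption drives the RSD well above 1.

"Mean standard deviation" of the reference is the arithmetic mean over
wavenumbers of the per-wavenumber sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError, SampleSizeError
from .spectra import Region, SpectrumSeries, region_indices

__all__ = [
    "RSDProfile",
    "pointwise_std",
    "rsd_profile",
    "DEFAULT_WATER_TARGET",
    "DEFAULT_CO2_TARGET",
    "DEFAULT_REFERENCE",
]

# conventional comparison regions (cm^-1)
DEFAULT_WATER_TARGET = Region(1200.0, 2100.0)
DEFAULT_CO2_TARGET = Region(2300.0, 2400.0)
DEFAULT_REFERENCE = Region(4800.0, 5000.0)


@dataclass
class RSDProfile:
    wavenumbers: np.ndarray
    rsd: np.ndarray
    target_region: Region
    reference_region: Region
    reference_mean_std: float

    def __post_init__(self) -> None:
        if self.reference_mean_std <= 0:
            raise DegenerateReferenceError("reference mean std must be > 0")

    @property
    def median(self) -> float:
        return float(np.median(self.rsd))

    @property
    def mean(self) -> float:
        return float(np.mean(self.rsd))


def pointwise_std(series: SpectrumSeries, r: Region) -> np.ndarray:
    """Sample (n-1) standard deviation across replicates at each axis point in r."""
    if len(series) < 3:
        raise SampleSizeError(
            f"need >= 3 replicates for a pointwise std, got {len(series)}"
        )
    i_lo, i_hi = region_indices(series.wavenumbers, r)
    block = series.stack()[:, i_lo : i_hi + 1]
    return np.std(block, axis=0, ddof=1)


def rsd_profile(
    series: SpectrumSeries,
    target: Region = DEFAULT_WATER_TARGET,
    reference: Region = DEFAULT_REFERENCE,
) -> RSDProfile:
    """RSD(v) = std_target(v) / mean(std_reference) over the target region."""
    std_t = pointwise_std(series, target)
    std_r = pointwise_std(series, reference)
    ref_mean = float(np.mean(std_r))
    # identical replicates leave only float rounding (~1e-17 of the signal)
    scale = float(np.mean(np.abs(series.stack()))) + 1e-300
    if ref_mean <= 1e-14 * scale:
        raise DegenerateReferenceError(
            "reference-region standard deviation is zero: replicates are "
            "identical (noiseless synthetic data?); RSD is undefined"
        )
    i_lo, i_hi = region_indices(series.wavenumbers, target)
    return RSDProfile(
        wavenumbers=series.wavenumbers[i_lo : i_hi + 1].copy(),
        rsd=std_t / ref_mean,
        target_region=target,
        reference_region=reference,
        reference_mean_std=ref_mean,
    )
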