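"""Exception hierarchy for atmcorr.

All domain errors derive from :class:`AtmcorrError` so callers (and the CLI)
can catch one base class.
"""


class AtmcorrError(Exception):
    """Base class for all atmcorr errors."""


class SpectrumParseError(AtmcorrError):
    """A spectrum file could not be parsed (carries the offending line)."""


class TooShortError(AtmcorrError):
    """A spectrum or segment has fewer points than the operation requires."""


class AxisError(AtmcorrError):
    """Wavenumber axes are non-monotonic or differ where they must match."""


class RegionError(AtmcorrError):
    """A wavenumber region does not overlap the axis or is malformed."""


class UnitError(AtmcorrError):
    """File is in unsupported units (e.g. transmittance instead of absorbance)."""


class UnsupportedDialectError(AtmcorrError):
    """JCAMP-DX file uses a dialect this reader does not handle."""


class EmptySeriesError(AtmcorrError):
    """A spectrum series contains no spectra."""


class ShapeError(AtmcorrError):
    """Vector lengths of paired inputs disagree."""


class DegenerateDifferenceError(AtmcorrError):
    """Difference spectrum is below the noise floor; no correction is possible."""


class PairingError(AtmcorrError):
    """A series is too short to form correction pairs."""


class SampleSizeError(AtmcorrError):
    """Too few replicates for a statistic."""


class DegenerateReferenceError(AtmcorrError):
    """Reference-region standard deviation is zero (identical replicates)."""


class ConfigError(AtmcorrError):
    """A configuration file or object is invalid."""


class RankError(AtmcorrError):
    """Requested latent-variable count is out of bounds."""


class FoldSizeError(AtmcorrError):
    """A cross-validation fold is too small for the requested model size."""
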