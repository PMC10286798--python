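"""Exception and warning types shared across the package."""


class SpectraGrowError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpectrumError(SpectraGrowError, ValueError):
    """A spectral distribution violates its invariants (unsorted grid, negative
    flux, too few points)."""


class EmptyBandError(SpectraGrowError, ValueError):
    """The spectrum carries no support inside the 400-750 nm analysis window,
    or a fraction is requested from an all-zero band set."""


class LabelParseError(SpectraGrowError, ValueError):
    """A treatment label does not match the B/G/R/FR/WW/EQW grammar."""


class ConstraintError(SpectraGrowError, ValueError):
    """Fraction-ratio inputs violate the closure constraint (the four waveband
    fractions must sum to one)."""


class SingularDesignError(SpectraGrowError, ValueError):
    """The regression design matrix is rank deficient and no penalty was
    requested."""


class NoRootError(SpectraGrowError, RuntimeError):
    """The calibration target lies outside the mass range reachable within the
    quantum-use-efficiency bracket."""


class NonMonotoneError(SpectraGrowError, RuntimeError):
    """Harvest mass did not increase across the calibration bracket, so a
    bracketing root-finder cannot be trusted."""


class IntegrationError(SpectraGrowError, RuntimeError):
    """The ODE solver failed to integrate a schedule segment."""


class ConfigError(SpectraGrowError, ValueError):
    """An environment recipe or run configuration is missing required fields."""


class DataCorruptionError(SpectraGrowError, RuntimeError):
    """A packaged data file does not match its recorded checksum."""


class OutOfRangeError(SpectraGrowError, ValueError):
    """A physiological correlation was evaluated outside its stated validity
    range (e.g. carboxylation conductance outside 5-40 degC)."""


class OutOfDomainWarning(UserWarning):
    """A regression prediction was requested outside the fraction-ratio domain
    spanned by the training data."""


class ModelValidityWarning(UserWarning):
    """The simulation left the region where the growth model is physically
    meaningful (negative non-structural mass, CO2 below compensation)."""
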