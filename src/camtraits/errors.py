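"""Exception hierarchy shared across the analysis modules."""


class CamTraitsError(Exception):
    """Base class for all package-specific errors."""


class DegenerateRecordError(CamTraitsError):
    """A drying-curve record violates its invariants (e.g. no saturated water)."""


class NoDrivingForceError(CamTraitsError):
    """The vapour-pressure gradient is zero or negative; conductance is undefined."""


class NoPlateauError(CamTraitsError):
    """No turgor-loss breakpoint is identifiable on the conductance curve."""


class EmptyWindowError(CamTraitsError):
    """The g_min averaging window contains no points."""


class InsufficientDataError(CamTraitsError):
    """Too few observations for the requested fit."""


class UnknownUnitError(CamTraitsError):
    """A conductance unit outside the supported set."""


class DuplicateSampleError(CamTraitsError):
    """Two titration samples share the same design coordinates."""


class OrphanTaxonError(CamTraitsError):
    """A data taxon has no matching tree tip and no lump rule."""


class ConfigError(CamTraitsError):
    """An analysis configuration failed validation."""
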