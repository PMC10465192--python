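"""Exception types shared across the package."""


class SupfieldError(Exception):
    """Base class for package-specific errors."""


class DensityError(SupfieldError, ValueError):
    """Genotype densities violate the simplex constraint."""


class FieldRangeError(SupfieldError, ValueError):
    """A field term (B or the effective survival) left its valid range.

    For in-range parameters the initiator term stays in [beta, 1] and the
    effective survival in [0, P_i]; leaving those ranges indicates an
    out-of-domain parameter combination and is raised with diagnostics
    rather than silently clamped.
    """


class PopulationCollapseError(SupfieldError, RuntimeError):
    """Every genotype reached zero effective survival in one update."""


class ThresholdUndefinedError(SupfieldError, ValueError):
    """No threshold density exists (no kin assortativity, phi_ii = 1)."""


class ConfigError(SupfieldError, ValueError):
    """A run configuration failed validation."""
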