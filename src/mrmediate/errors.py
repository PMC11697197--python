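"""Exception hierarchy for mrmediate."""


class MrmediateError(Exception):
    """Base class for all package errors."""


class ColumnMappingError(MrmediateError, KeyError):
    """A mapped column is missing from the input file."""


class EmptyInputError(MrmediateError, ValueError):
    """No valid rows remain after validation, or an empty table was supplied."""


class EmptyOverlapError(MrmediateError, ValueError):
    """Exposure and outcome tables share no SNPs after harmonization."""


class SnpNotInLdError(MrmediateError, KeyError):
    """A record's SNP identifier is absent from the supplied LD matrix."""


class DegenerateInstrumentError(MrmediateError, ValueError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""


class InsufficientSnpsError(MrmediateError, ValueError):
    """An estimator was called with fewer SNPs than it requires."""


class ConfigurationError(MrmediateError, ValueError):
    """An analysis or simulation configuration is invalid."""


class UndefinedProportionError(MrmediateError, ZeroDivisionError):
    """Proportion mediated is undefined because the total effect is zero."""
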