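"""Exception hierarchy for stratmr."""


class StratMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StratMRError):
    """A config file, column map, or parameter set is malformed."""


class ValidationError(StratMRError):
    """Input data violate a declared invariant (carries row context)."""
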