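"""Exception hierarchy for the battery toolkit."""


class CogbatError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CogbatError):
    """A task configuration violates its invariants."""


class InputError(CogbatError):
    """An agent or caller supplied an out-of-contract value."""


class InsufficientDataError(CogbatError):
    """A session does not contain enough trials for the requested metric."""


class DegenerateDesignError(CogbatError):
    """The choice set carries no information about the parameter of interest."""


class PracticeGateError(CogbatError):
    """The responder failed the practice accuracy gate on every allowed attempt."""


class FitError(CogbatError):
    """Maximum-likelihood optimisation failed on every restart."""


class SchemaError(CogbatError):
    """A table or log is missing required columns or fields."""
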