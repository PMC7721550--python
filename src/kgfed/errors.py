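"""Shared exception types for the federation pipeline."""


class KgfedError(Exception):
    """Base class for engine errors."""


class RegistryError(KgfedError):
    """A knowledge source is unknown, unreachable, or misconfigured."""


class SchemaValidationError(KgfedError):
    """A transition map references names outside the concept model."""


class PlanningError(KgfedError):
    """No registered service can answer a step of the query path."""


class FederationError(KgfedError):
    """A knowledge source's response violates the invocation contract."""


class MergeError(KgfedError):
    """Per-segment results cannot be merged into one coherent graph."""
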