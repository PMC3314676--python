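"""Exception hierarchy shared by all hiernet modules."""


class HiernetError(Exception):
    """Base class for all hiernet errors."""


class EdgeListParseError(HiernetError):
    """A line of an edge-list file could not be parsed."""

    def __init__(self, lineno: int, message: str) -> None:
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class ValidationError(HiernetError):
    """A network violates a structural invariant (e.g. non-positive weight)."""


class UsageError(HiernetError):
    """An operation was called on an incompatible kind of network."""


class LookupNodeError(HiernetError, KeyError):
    """A node identifier is not present in the network."""


class ParameterError(HiernetError, ValueError):
    """A generator or analysis parameter is out of its admissible range."""


class RandomizationError(HiernetError):
    """Degree-preserving randomization could not satisfy its constraints."""
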