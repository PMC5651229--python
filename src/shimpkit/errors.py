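"""Exception hierarchy shared across the package."""


class ShimpError(Exception):
    """Base class for all package-specific errors."""


class InvalidTraceError(ShimpError, ValueError):
    """A velocity trace violates its invariants (too short, non-finite, ...)."""


class SchemaError(ShimpError, ValueError):
    """An input file does not match the documented schema."""


class IntegrityError(ShimpError, ValueError):
    """An input file parses but its content is internally inconsistent."""


class SimulationError(ShimpError, ValueError):
    """A simulation specification is unsatisfiable (e.g. event beyond the trace)."""
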