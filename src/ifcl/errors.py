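"""Exception hierarchy for the ifcl package."""


class IfclError(Exception):
    """Base class for all package-specific errors."""


class InputError(IfclError):
    """An input file is unreadable, empty, or structurally invalid."""


class ConfigurationError(IfclError):
    """A user-supplied option is out of range or inconsistent."""


class DataError(IfclError):
    """The data violate a precondition (fully-missing column, constant column, ...)."""


class StructuralError(IfclError):
    """A graph operation violates DAG structure (self-loop, cycle)."""


class NumericalError(IfclError):
    """A numerical routine failed (singular design matrix, fit failure)."""


class ConsistencyError(IfclError):
    """Two objects that must refer to the same data disagree."""


class CapabilityError(IfclError):
    """A request exceeds an operation's declared capability (e.g. exhaustive n)."""
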