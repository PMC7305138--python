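"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`CsxrfError` so callers (and the CLI) can distinguish usage errors
from bugs.
"""


class CsxrfError(Exception):
    """Base class for all deliberate csxrf errors."""


class ConfigError(CsxrfError, ValueError):
    """A configuration file or object violates its schema or invariants."""


class IntegrityError(CsxrfError, ValueError):
    """A data structure or file is internally inconsistent."""


class SchemaVersionError(IntegrityError):
    """An HDF5 file declares an unsupported schema version."""


class PlanError(CsxrfError, ValueError):
    """A scan plan is invalid (empty, out of grid, duplicated positions)."""
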