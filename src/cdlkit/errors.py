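"""Exception hierarchy.

``CdlkitError`` is the base for data/integrity problems; the CLI maps it to
exit code 2 (usage errors exit 1).
"""


class CdlkitError(Exception):
    """Base class for data and integrity errors raised by cdlkit."""


class ParseError(CdlkitError):
    """Malformed coordinate input (carries a line number where possible)."""


class TableError(CdlkitError):
    """Restraint-table schema or integrity violation."""


class GeometryError(CdlkitError):
    """Degenerate geometry: zero-length rays, collinear torsion frames, infeasible internals."""
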