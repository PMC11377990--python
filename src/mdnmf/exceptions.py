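"""Exception hierarchy.

All package errors derive from :class:`MdnmfError` so callers can catch one
base class; the leaves also subclass the matching builtin so generic code
(``except ValueError``) keeps working.
"""


class MdnmfError(Exception):
    """Base class for all mdnmf errors."""


class FormatError(MdnmfError, ValueError):
    """Malformed input file (empty, short row, bad value...)."""


class ParameterError(MdnmfError, ValueError):
    """Invalid parameter value (rank out of range, K >= n, ...)."""


class DegenerateInputError(MdnmfError, ValueError):
    """Input degenerate for the requested operation (e.g. all-zero profiles)."""


class DivergenceError(MdnmfError, RuntimeError):
    """Non-finite objective encountered during optimization."""
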