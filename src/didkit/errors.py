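"""Exception hierarchy for didkit.

All didkit errors derive from :class:`DidkitError` so callers can catch the
package's failures with a single except clause while still distinguishing
bad user input from malformed files or inconsistent configuration.
"""


class DidkitError(Exception):
    """Base class for all didkit errors."""


class InputError(DidkitError, ValueError):
    """A caller-supplied value violates an operation's precondition."""


class ValidationError(DidkitError, ValueError):
    """Data in a file or record violates an invariant (e.g. duplicate keys)."""


class FormatError(DidkitError, ValueError):
    """A file does not conform to the expected dialect (header mismatch etc.)."""


class ConfigurationError(DidkitError, ValueError):
    """Rankings, lexicons, remap tables or options are inconsistent."""


class ConsistencyError(DidkitError, ValueError):
    """Cross-stage inputs do not line up (missing normalizations, source sets)."""
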