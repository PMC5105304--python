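"""Package exception types."""


class TipcallError(Exception):
    """Base class for package errors."""


class InvariantError(TipcallError, ValueError):
    """A domain-type invariant was violated; message names the invariant."""


class SiteIncompatibleError(TipcallError, ValueError):
    """Target site makes the requested insertion parameters unidentifiable."""


class PlacementError(TipcallError, RuntimeError):
    """Could not place a feature after bounded retries."""


class NotL1InsertionError(TipcallError, ValueError):
    """Allele does not parse as an L1 insertion."""


class FormatError(TipcallError, ValueError):
    """Malformed record in an on-disk file; message carries the line number."""
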