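"""Exception hierarchy shared across the toolkit."""


class BeetrackError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BeetrackError):
    """An input file could not be parsed; the message names the offending record."""


class ValidationError(BeetrackError):
    """Parsed data violates a structural invariant (duplicate ids, bad polygon...)."""


class ConfigError(BeetrackError):
    """A configuration object is internally inconsistent."""


class MaskOverlapError(ValidationError):
    """Result masks within a frame overlap; carries the offending (frame, id, id) pairs."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"frame {f}: ids {a}/{b}" for f, a, b in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" (+{len(self.pairs) - 10} more)"
        super().__init__(f"overlapping result masks: {shown}{more}")
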