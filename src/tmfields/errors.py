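"""Exception types shared across the package."""


class CapacityError(ValueError):
    """An exact operation was asked to enumerate a space above its guard."""


class PositivityError(ValueError):
    """A probability table violates the strict-positivity hypothesis."""


class AlignmentError(ValueError):
    """Per-layer sample matrices do not share sample identity/order."""
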