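"""Exception types shared across the package."""


class SpheroflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(SpheroflowError, ValueError):
    """A channel/obstacle specification violates its invariants."""


class OutOfDomainError(SpheroflowError, ValueError):
    """A point lies outside the flow domain (inside the obstacle or
    outside the channel footprint)."""


class UndefinedHistogramError(SpheroflowError, ValueError):
    """An orientation histogram cannot be formed (zero total gradient weight)."""
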