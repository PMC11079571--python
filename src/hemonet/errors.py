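"""Exception types shared across the package."""


class HemonetError(Exception):
    """Base class for package-specific errors."""


class TopologyError(HemonetError):
    """The vascular graph violates a structural requirement (cycle,
    unreachable node, wrong junction degrees)."""


class OrientationError(HemonetError):
    """A profile was (re-)oriented inconsistently, e.g. apex-first applied
    twice."""


class IncompleteComponentError(HemonetError):
    """Ground-truth data is missing at one end of a vascular component."""


class DegenerateProfileError(HemonetError):
    """A profile/field is degenerate for the requested operation (all zero,
    empty mask, ...)."""


class ModelStateError(HemonetError):
    """A model was used before training or with mismatched inputs."""
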