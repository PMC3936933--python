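"""Exception hierarchy.

``MolcanvasError`` is the common base; ``InputError`` marks user-input
problems that the CLI maps to exit code 2.
"""


class MolcanvasError(Exception):
    """Base class for all molcanvas errors."""


class InputError(MolcanvasError):
    """A problem with user-supplied input (CLI exit code 2)."""


class EmptyInputError(InputError):
    """Input text contained no parseable records."""


class MalformedRecordError(InputError):
    """A record line was too short / unparseable and nothing survived."""


class InconsistentModelsError(InputError):
    """Models of a docked ensemble disagree in atom count or ordering."""


class NoAtomsError(InputError):
    """An operation requiring atoms received a structure without any."""


class NoFeaturesError(MolcanvasError):
    """A distance transform was requested on a mask with no feature voxels."""


class UnknownSchemeError(InputError):
    """Color scheme name not recognized."""


class UnknownRepresentationError(InputError):
    """Representation name not recognized."""


class InvalidSpecError(InputError):
    """Fixture specification is invalid."""


class BehindCameraError(MolcanvasError):
    """Point projects at or behind the eye plane of a perspective camera."""
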