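"""Exception hierarchy.

Every error carries a stable ``exit_code`` so the command-line front end can
map failure classes to distinct process exit statuses (see docs/methods.md).
"""


class OsteokitError(Exception):
    """Base class for all package errors."""

    exit_code: int = 1


# --- shape_model -----------------------------------------------------------

class ShapeMismatchError(OsteokitError):
    """Training clouds are ragged or shapes disagree with the model."""

    exit_code = 3


class RankDeficientError(OsteokitError):
    """Normal matrix singular or ill-conditioned (too few / collinear specimens)."""

    exit_code = 3


class UnknownParameterError(OsteokitError):
    """A parameter name is not part of the model."""

    exit_code = 3


class MissingSubsetError(OsteokitError):
    """Requested coefficient subset absent and no training set attached."""

    exit_code = 4


class MinimumParameterError(OsteokitError):
    """Fewer parameters supplied than the configured per-bone minimum."""

    exit_code = 4


class FormatVersionError(OsteokitError):
    """Model store file declares an unknown schema version."""

    exit_code = 5


class ChecksumError(OsteokitError):
    """Model store file failed its integrity check."""

    exit_code = 5


# --- geometry3d ------------------------------------------------------------

class DegenerateSliceError(OsteokitError):
    """Slice points are collinear (or coincident) — closed curve undefined."""

    exit_code = 6


class EmptyResultError(OsteokitError):
    """Nothing lies on the kept side of a clipping plane."""

    exit_code = 8


class SelfIntersectionWarning(UserWarning):
    """Consecutive slice curves cross; loft may self-intersect (not fatal)."""


# --- plate_design ----------------------------------------------------------

class DuplicatePointError(OsteokitError):
    """Reference-line points must be distinct."""

    exit_code = 6


class InsufficientCoverageError(OsteokitError):
    """Too few bone points inside the plate corridor to form a patch."""

    exit_code = 7


class SelfIntersectionError(OsteokitError):
    """Offsetting by the requested thickness inverts the surface locally."""

    exit_code = 7


class HoleOverlapError(OsteokitError):
    """Screw-hole footprints overlap on the plate."""

    exit_code = 7


class HoleOffPlateError(OsteokitError):
    """A screw hole does not fit inside the plate interior."""

    exit_code = 7


class NotWatertightError(OsteokitError):
    """A watertight solid was required but the mesh is open."""

    exit_code = 8


# --- mandible_axis ---------------------------------------------------------

class ZeroLengthError(OsteokitError):
    """Etalon length must be strictly positive."""

    exit_code = 9


class MissingLandmarkError(OsteokitError):
    """A required cephalometric landmark is absent."""

    exit_code = 9


class DegenerateLineError(OsteokitError):
    """Two coincident points cannot define a line."""

    exit_code = 9


class ParallelPlanesError(OsteokitError):
    """Occlusion and mandibular constructions yield parallel planes."""

    exit_code = 9


# --- synthetic_data --------------------------------------------------------

class ConfigError(OsteokitError):
    """Generator configuration is internally inconsistent."""

    exit_code = 2
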