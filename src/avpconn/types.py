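"""Domain types shared by every pipeline stage.

All geometry is carried in nanometres; neuron identifiers are opaque strings
so ids from any reconstruction platform fit.  The background segmentation is
encoded with the reserved partner id ``BACKGROUND_ID`` and is only removed by
the explicit synapse filter, never at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GeometryError, ValidationError

#: Reserved partner id for contacts onto the background segmentation.
BACKGROUND_ID = "0"

#: Column order of a synapse table on disk.
SYNAPSE_COLUMNS = ["pre_id", "post_id", "x_nm", "y_nm", "z_nm", "cleft_score"]

#: Column order of an annotation table on disk.
ANNOTATION_COLUMNS = ["neuron_id", "cell_class", "hemisphere", "subtype"]


@dataclass(frozen=True)
class SynapseRecord:
    """One pre->post synaptic contact with 3-D position (nm) and cleft score."""

    pre_id: str
    post_id: str
    position: np.ndarray  # shape (3,), nm
    cleft_score: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(f"synapse position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.cleft_score < 0:
            raise ValidationError(f"cleft_score must be >= 0, got {self.cleft_score}")
        if not self.pre_id or not self.post_id:
            raise ValidationError("pre_id and post_id must be non-empty")


@dataclass(frozen=True)
class NeuronAnnotation:
    """Identity, controlled cell-class label and hemisphere of one neuron."""

    neuron_id: str
    cell_class: str
    hemisphere: str
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValidationError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if not self.neuron_id:
            raise ValidationError("neuron_id must be non-empty")


@dataclass
class RegionHull:
    """Convex neuropil boundary given by its vertex set (nm).

    ``subtract`` optionally names a second hull whose interior is excluded
    from membership (used where one tessellation overlaps a neighbouring
    neuropil, e.g. a medulla hull that swallows part of the lobula).
    """

    name: str
    vertices: np.ndarray  # (n, 3) nm
    subtract: Optional[str] = None

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 3 or verts.shape[0] < 4:
            raise GeometryError(f"hull {self.name!r} needs >= 4 vertices of dimension 3")
        if not np.all(np.isfinite(verts)):
            raise GeometryError(f"hull {self.name!r} has non-finite vertices")
        # coplanarity check: rank of centred vertex cloud must be 3
        centred = verts - verts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(verts).max())) < 3:
            raise GeometryError(f"hull {self.name!r} vertices are coplanar")
        self.vertices = verts


@dataclass(frozen=True)
class EllipseFit:
    """Planar elliptical span: centroid, semi-axes, orientation.

    ``angle_deg`` is measured from the dorsal-ventral (second, vertical)
    axis of the fitting plane, increasing toward the first axis, and lies
    in [0, 180).  ``ratio`` is semi-major over semi-minor.
    """

    centroid: tuple
    semi_major: float
    semi_minor: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValidationError(
                f"ellipse axes must satisfy a >= b > 0, got a={self.semi_major}, b={self.semi_minor}"
            )
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValidationError(f"angle must lie in [0, 180), got {self.angle_deg}")

    @property
    def ratio(self) -> float:
        return self.semi_major / self.semi_minor


@dataclass
class MedullaColumn:
    """One retinotopic medulla column anchored by a columnar neuron.

    The axis is the unit distal->proximal direction; depth bounds are the
    3rd/97th percentile of the anchor neuron's synapse projections (nm).
    """

    column_id: str
    q: int
    r: int
    axis: np.ndarray  # unit 3-vector
    anchor: np.ndarray  # nm, axis origin
    depth_lo: float
    depth_hi: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise GeometryError(f"column {self.column_id}: axis must be unit length (|axis|={n})")
        if not self.depth_lo < self.depth_hi:
            raise GeometryError(f"column {self.column_id}: depth_lo must be < depth_hi")
        self.axis = axis
        self.anchor = np.asarray(self.anchor, dtype=float)


@dataclass
class EyeMap:
    """Assignment of medulla columns to ommatidial viewing directions.

    ``directions`` maps column_id -> (azimuth_deg, elevation_deg); matched
    assignments are injective.  ``offset``/``mirrored`` record the lattice
    transform that produced the alignment.
    """

    directions: dict
    equator: set
    unmatched: list
    offset: tuple = (0, 0)
    mirrored: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for cid, (az, el) in self.directions.items():
            if not (-180.0 <= az < 180.0) or not (-90.0 <= el <= 90.0):
                raise ValidationError(f"column {cid}: direction ({az}, {el}) out of range")
            key = (round(az, 9), round(el, 9))
            if key in seen:
                raise ValidationError(f"eye map not injective at direction {key}")
            seen.add(key)


@dataclass(frozen=True)
class NTProfile:
    """Per-neuron mean neurotransmitter probability vector."""

    neuron_id: str
    probabilities: np.ndarray
    classes: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValidationError("NT probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class AxialStats:
    """Axial (orientation) Rayleigh statistics on doubled angles."""

    n: int
    mean_angle_deg: float
    resultant_length: float
    z: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p value must lie in (0, 1], got {self.p_value}")
        if not (0.0 <= self.resultant_length <= 1.0 + 1e-12):
            raise ValidationError(f"resultant length must lie in [0, 1], got {self.resultant_length}")


@dataclass
class Occupancy:
    """Fraction of one MeTu neuron's qualifying sites nearest each column."""

    metu_id: str
    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fractions:
            total = sum(self.fractions.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValidationError(f"occupancy of {self.metu_id} sums to {total}, expected 1")


@dataclass
class ColumnWeightField:
    """Per-column direct/indirect pathway weights for one ER neuron."""

    er_id: str
    direct: dict = field(default_factory=dict)
    indirect: dict = field(default_factory=dict)
    covered_columns: int = 0
    outline: list = field(default_factory=list)
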