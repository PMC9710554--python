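"""Ligand-centric internal coordinate frames and the spatial similarity score.

The internal frame of a ligand residue is defined so that

* its Cα atom is the origin,
* its Cβ atom lies on the positive x-axis,
* its carbonyl C lies in the xy-plane, and
* its amide N has a negative z-coordinate.

Glycine (and any residue missing Cβ) is handled through a virtual Cβ placed
by ideal tetrahedral geometry, so every residue type owns a frame and the
similarity score is total over the 20 canonical types.

The spatial similarity between two residues R1, R2 expressed in a common
coordinate system is

    s(R1, R2) = fd * |Cα1 - Cα2|
              + fo * angle(Cβ1 - Cα1, Cβ2 - Cα2)      (primary orientation)
              + fs * angle(C1 - Cα1, C2 - Cα2)        (secondary orientation)

with angles in radians.  Radians keep the orientation terms commensurate
with the distance term under the default weights (fd = 1.0 / Å,
fo = fs = 2.0); with degrees the orientation terms would dominate by two
orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FrameError, GeometryError

#: Virtual Cβ bond length (Å) and ideal tetrahedral angle cosine.
VIRTUAL_CB_LENGTH = 1.53
_TETRAHEDRAL_COS = -1.0 / 3.0

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class SimilarityWeights:
    """Weights of the distance / orientation terms of the similarity score.

    ``fd`` is per Å; ``fo`` and ``fs`` are dimensionless (angles in radians).
    """

    fd: float = 1.0
    fo: float = 2.0
    fs: float = 2.0

    def __post_init__(self):
        if self.fd < 0 or self.fo < 0 or self.fs < 0:
            raise GeometryError("similarity weights must be non-negative")


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise GeometryError(f"zero-length {what}")
    return v / n


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in radians, robust near 0 and pi."""
    a = _unit(np.asarray(a, dtype=float), "orientation vector")
    b = _unit(np.asarray(b, dtype=float), "orientation vector")
    return float(np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b)))


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place an ideal Cβ from backbone N, Cα, C.

    Tetrahedral construction: the Cβ direction makes the ideal 109.47° angle
    with both the Cα→N and Cα→C bonds, at 1.53 Å from Cα.  Two mirror
    placements satisfy those constraints; the one matching L-amino acids is
    returned (the construction is rotation- and translation-equivariant but,
    like the amino acids themselves, chiral).
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    u = _unit(n - ca, "N-CA bond")
    v = _unit(c - ca, "C-CA bond")
    w = np.cross(u, v)
    wn = np.linalg.norm(w)
    if wn < _COLLINEAR_TOL:
        raise GeometryError("N, CA, C are collinear")
    w /= wn
    dot = float(np.dot(u, v))
    alpha = _TETRAHEDRAL_COS / (1.0 + dot)
    rad2 = 1.0 - alpha * alpha * 2.0 * (1.0 + dot)
    beta = np.sqrt(max(rad2, 0.0))
    # +beta along u x v selects the L-configuration (validated against the
    # ideal alanine fixture).
    direction = alpha * (u + v) + beta * w
    return ca + VIRTUAL_CB_LENGTH * _unit(direction)


@dataclass
class ResiduePose:
    """Minimal geometric description of a residue for frame building and
    similarity scoring."""

    calpha: np.ndarray
    cbeta: np.ndarray
    carbonyl_c: np.ndarray
    amide_n: np.ndarray | None
    residue_type: str = "UNK"
    all_atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def primary_orientation(self) -> np.ndarray:
        return np.asarray(self.cbeta) - np.asarray(self.calpha)

    @property
    def secondary_orientation(self) -> np.ndarray:
        return np.asarray(self.carbonyl_c) - np.asarray(self.calpha)


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal frame; rows of ``axes`` are x, y, z."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3)

    def to_internal(self, xyz: np.ndarray) -> np.ndarray:
        return self.axes @ (np.asarray(xyz, dtype=float) - self.origin)

    def to_external(self, xyz: np.ndarray) -> np.ndarray:
        return self.axes.T @ np.asarray(xyz, dtype=float) + self.origin


def build_frame(residue: ResiduePose) -> Frame:
    """Internal coordinate frame of a ligand residue.

    Postconditions (on the residue's own atoms transformed by the frame):
    Cα at the origin, Cβ at (d, 0, 0) with d > 0, carbonyl C with z = 0,
    amide N with z < 0.
    """
    ca = np.asarray(residue.calpha, dtype=float)
    cb = np.asarray(residue.cbeta, dtype=float)
    c = np.asarray(residue.carbonyl_c, dtype=float)
    if residue.amide_n is None:
        raise FrameError("amide N required to fix frame handedness")
    n = np.asarray(residue.amide_n, dtype=float)
    try:
        ex = _unit(cb - ca, "CA-CB bond")
    except GeometryError as exc:
        raise FrameError(str(exc)) from exc
    vc = c - ca
    vy = vc - np.dot(vc, ex) * ex
    if np.linalg.norm(vy) < _COLLINEAR_TOL:
        raise FrameError("carbonyl C collinear with CA-CB axis")
    ey = vy / np.linalg.norm(vy)
    ez = np.cross(ex, ey)
    # Two frames satisfy "C in the xy-plane"; pick the one placing N below it.
    if np.dot(n - ca, ez) > 0:
        ey, ez = -ey, -ez
    return Frame(origin=ca, axes=np.array([ex, ey, ez]))


def transform_pose(pose: ResiduePose, frame: Frame) -> ResiduePose:
    """Express a pose in the given frame's internal coordinates."""
    return ResiduePose(
        calpha=frame.to_internal(pose.calpha),
        cbeta=frame.to_internal(pose.cbeta),
        carbonyl_c=frame.to_internal(pose.carbonyl_c),
        amide_n=None if pose.amide_n is None else frame.to_internal(pose.amide_n),
        residue_type=pose.residue_type,
        all_atoms={k: frame.to_internal(v) for k, v in pose.all_atoms.items()},
    )


def spatial_similarity(r1: ResiduePose, r2: ResiduePose,
                       w: SimilarityWeights = SimilarityWeights()) -> float:
    """Distance-orientation similarity score (lower = more similar; 0 iff
    identical position and orientations).  Both poses must already be
    expressed in one common coordinate system."""
    d = float(np.linalg.norm(np.asarray(r1.calpha, dtype=float)
                             - np.asarray(r2.calpha, dtype=float)))
    ang_p = vector_angle(r1.primary_orientation, r2.primary_orientation)
    ang_s = vector_angle(r1.secondary_orientation, r2.secondary_orientation)
    return w.fd * d + w.fo * ang_p + w.fs * ang_s


def random_rigid_motion(rng: np.random.Generator,
                        max_translation: float = 20.0):
    """Uniformly random rotation + bounded translation; returns (R, t).

    Helper for tests and fixtures: apply as ``x -> R @ x + t``.
    """
    # QR of a Gaussian matrix gives a Haar-ish rotation after sign fixing.
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return q, t
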