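"""Superquadric geometry and the synthetic shape database.

Superquadrics are a compact implicit-surface family spanning boxes,
ellipsoids, spheres, plates, and cylinders.  Each shape is described by
nine free parameters: three semi-axis scales ``A`` (meters), three shape
exponents ``eps`` (dimensionless; values near 0 give squared edges, 1
gives round edges), and three rotation angles ``theta`` (radians).

The implicit function used throughout is

    F(x, y, z) = (|x|/A1)^(2/eps1) + (|y|/A2)^(2/eps2) + (|z|/A3)^(2/eps3)

with F < 1 inside, F = 1 on the surface and F > 1 outside.  The 2/eps
exponent convention reproduces the standard special cases (a sphere at
eps = 1, boxes as eps -> 0).

This module also hosts the symmetry-aware enumeration of the 36-stimulus
design used for augmented tuning curves (4 base shapes x 4 sizes x 4
orientations, deduplicated under each base shape's rotational symmetry).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Superquadric",
    "ShapeDatabase",
    "StimulusSet",
    "inside_outside",
    "implicit_surface",
    "rotation_matrix",
    "euler_angles",
    "canonicalize",
    "sample_database",
    "enumerate_stimuli",
    "base_stimulus_shapes",
    "stimulus_features",
    "ORIENTATION_NAMES",
    "ORIENTATION_ANGLES",
]

SPHERE_LIKE = "sphere-like"
BOX_LIKE = "box-like"
CYLINDER_LIKE = "cylinder-like"
PLATE_LIKE = "plate-like"

#: Orientation design for the augmented tuning curves: each pose is a
#: rotation of the upright base shape about the horizontal (x) axis.
ORIENTATION_NAMES = ("vertical", "horizontal", "tilted-forward", "tilted-backward")
ORIENTATION_ANGLES = (0.0, np.pi / 2, np.pi / 4, -np.pi / 4)


class InvalidParameterError(ValueError):
    """Raised when superquadric parameters are outside their domain."""


@dataclass(frozen=True)
class Superquadric:
    """A superquadric shape: scales (m), exponents, rotation (rad).

    ``label`` tags the shape class (sphere-like, box-like, cylinder-like,
    plate-like); it determines which symmetry rules apply during
    canonicalization.
    """

    A1: float
    A2: float
    A3: float
    eps1: float
    eps2: float
    eps3: float
    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    label: str = BOX_LIKE

    def __post_init__(self) -> None:
        if min(self.A1, self.A2, self.A3) <= 0:
            raise InvalidParameterError("semi-axis scales A must be positive")
        if min(self.eps1, self.eps2, self.eps3) <= 0:
            raise InvalidParameterError("shape exponents eps must be positive")

    @property
    def scales(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3])

    @property
    def exponents(self) -> np.ndarray:
        return np.array([self.eps1, self.eps2, self.eps3])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])

    @property
    def params(self) -> np.ndarray:
        """The 9 free numeric parameters (scales, exponents, angles)."""
        return np.concatenate([self.scales, self.exponents, self.angles])

    def scaled(self, factor: float) -> "Superquadric":
        """Uniformly rescale all three semi-axes."""
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor, A3=self.A3 * factor)

    def rotation(self) -> np.ndarray:
        """World-to-object rotation matrix for this shape's angles."""
        return rotation_matrix(self.theta1, self.theta2, self.theta3)


def implicit_surface(points: np.ndarray, sq: Superquadric) -> np.ndarray:
    """Evaluate F at object-frame points of shape (..., 3).

    Safe for tiny exponents (2/eps can exceed 100): overflow saturates to
    +inf, which is a valid "far outside" value for root bracketing.
    """
    p = np.asarray(points, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        fx = (np.abs(p[..., 0]) / sq.A1) ** (2.0 / sq.eps1)
        fy = (np.abs(p[..., 1]) / sq.A2) ** (2.0 / sq.eps2)
        fz = (np.abs(p[..., 2]) / sq.A3) ** (2.0 / sq.eps3)
    return fx + fy + fz


def inside_outside(point, sq: Superquadric) -> float:
    """Inside-outside value F for a single object-frame point.

    F < 1 inside the shape, F = 1 on its surface, F > 1 outside.
    """
    return float(implicit_surface(np.asarray(point, dtype=float), sq))


def rotation_matrix(theta1: float, theta2: float, theta3: float) -> np.ndarray:
    """3x3 rotation matrix from the three superquadric angles.

    Equals Rz(-theta3) @ Ry(-theta2) @ Rx(-theta1); orthonormal with
    determinant +1.  Used as the world-to-object transform, i.e.
    ``x_obj = R @ x_world`` for points relative to the shape center.
    """
    c1, s1 = np.cos(theta1), np.sin(theta1)
    c2, s2 = np.cos(theta2), np.sin(theta2)
    c3, s3 = np.cos(theta3), np.sin(theta3)
    return np.array(
        [
            [c2 * c3, c1 * s3 + s1 * s2 * c3, s1 * s3 - c1 * s2 * c3],
            [-c2 * s3, c1 * c3 - s1 * s2 * s3, s1 * c3 + c1 * s2 * s3],
            [s2, -s1 * c2, c1 * c2],
        ]
    )


def euler_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`rotation_matrix`: recover (theta1, theta2, theta3).

    Handles the gimbal-lock case |sin theta2| = 1 by fixing theta3 = 0.
    """
    s2 = float(np.clip(R[2, 0], -1.0, 1.0))
    theta2 = np.arcsin(s2)
    if abs(s2) < 1.0 - 1e-12:
        theta1 = np.arctan2(-R[2, 1], R[2, 2])
        theta3 = np.arctan2(-R[1, 0], R[0, 0])
    else:
        # gimbal lock: theta1 and theta3 rotate about the same axis; put
        # the whole rotation into theta1 and fix theta3 = 0
        theta3 = 0.0
        theta1 = float(np.sign(s2)) * np.arctan2(R[0, 1], R[1, 1])
    return float(theta1), float(theta2), float(theta3)


def _signed_permutations() -> list[tuple[np.ndarray, np.ndarray]]:
    """The 24 rotations of the octahedral group as signed permutation
    matrices, paired with the axis permutation they induce."""
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            S = np.zeros((3, 3))
            for i, (j, s) in enumerate(zip(perm, signs)):
                S[i, j] = s
            if np.linalg.det(S) > 0.5:
                out.append((S, np.array(perm)))
    return out


_OCTAHEDRAL = _signed_permutations()


def _box_candidates(sq: Superquadric):
    """Equivalent (angles, scales, exponents) triples for a box-symmetric
    shape under the 24 octahedral relabelings.

    If S is a signed permutation with (S x)_i = s_i * x_{perm(i)}, then
    F_{A,eps}(R p) = F_{A',eps'}(S^T R p) with A'_j = A_{perm^-1(j)}, so
    (S^T R, A', eps') parameterizes the same surface.
    """
    R = sq.rotation()
    A, E = sq.scales, sq.exponents
    cands = []
    for S, perm in _OCTAHEDRAL:
        Rp = S.T @ R
        inv = np.argsort(perm)  # A'_j = A_{perm^-1(j)}
        angles = euler_angles(Rp)
        cands.append((angles, A[inv], E[inv]))
    return cands


def canonicalize(sq: Superquadric) -> Superquadric:
    """Map a shape to its canonical parameterization within its class.

    The same surface admits several superquadric parameterizations (a
    tall box equals a wide box on its end); restricting angles to a
    class-specific range makes the shape -> depth-map function invertible
    on canonical forms.  Rules:

    - true spheres (equal scales, eps = 1): all angles set to 0;
    - cylinder-like shapes (round cross-section about the object z axis):
      the spin angle theta3 is redundant and set to 0; the symmetry axis
      is flipped so theta1, theta2 lie in [-pi/2, pi/2];
    - box-like (also plate-like and non-spherical sphere-like) shapes:
      among the 24 octahedral relabelings, the one whose angles all lie
      closest to within +/- pi/4, ties broken lexicographically.

    Idempotent, and preserves the rendered surface to within the depth
    renderer's tolerance.
    """
    A, E = sq.scales, sq.exponents
    if np.allclose(A, A[0], rtol=1e-9) and np.allclose(E, 1.0, atol=1e-9):
        return replace(sq, theta1=0.0, theta2=0.0, theta3=0.0)

    if sq.label == CYLINDER_LIKE and abs(sq.A1 - sq.A2) < 1e-12 and abs(sq.eps1 - sq.eps2) < 1e-12:
        axis = sq.rotation()[2, :]  # object z axis in world coordinates
        if axis[2] < 0 or (axis[2] == 0 and (axis[1] < 0 or (axis[1] == 0 and axis[0] < 0))):
            axis = -axis
        theta2 = float(np.arcsin(np.clip(axis[0], -1.0, 1.0)))
        if abs(abs(axis[0]) - 1.0) < 1e-12:
            theta1 = 0.0
        else:
            theta1 = float(np.arctan2(-axis[1], axis[2]))
        return replace(sq, theta1=theta1, theta2=theta2, theta3=0.0)

    best = None
    best_key = None
    for angles, Ap, Ep in _box_candidates(sq):
        maxang = max(abs(a) for a in angles)
        key = (
            round(max(maxang - np.pi / 4, 0.0), 9),
            tuple(np.round(angles, 9)),
            tuple(np.round(Ap, 12)),
            tuple(np.round(Ep, 12)),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = (angles, Ap, Ep)
    angles, Ap, Ep = best
    return replace(
        sq,
        A1=float(Ap[0]), A2=float(Ap[1]), A3=float(Ap[2]),
        eps1=float(Ep[0]), eps2=float(Ep[1]), eps3=float(Ep[2]),
        theta1=angles[0], theta2=angles[1], theta3=angles[2],
    )


# ---------------------------------------------------------------------------
# Database sampling (the synthetic-data generator)
# ---------------------------------------------------------------------------

#: Squared-edge exponents follow a shifted exponential,
#: p(eps) = 10 H(eps - eta) exp(-(eps - eta)/0.1), eta = 0.01,
#: which keeps corners sharp but bounded away from the numerically
#: degenerate eps = 0.
EPS_SCALE = 0.1
EPS_SHIFT = 0.01

#: Semi-axis scales: object widths 2A between 0.02 m and 0.12 m.
A_MIN = 0.01
A_MAX = 0.06


@dataclass
class ShapeDatabase:
    """An ordered collection of superquadrics with a train/val split."""

    shapes: list
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.shapes)

    def __getitem__(self, i: int) -> Superquadric:
        return self.shapes[i]

    @property
    def labels(self) -> list:
        return [s.label for s in self.shapes]

    def params_matrix(self) -> np.ndarray:
        """(n, 9) matrix of shape parameters in database order."""
        return np.stack([s.params for s in self.shapes])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.params_matrix(),
            columns=["A1", "A2", "A3", "eps1", "eps2", "eps3", "theta1", "theta2", "theta3"],
        )
        df["label"] = self.labels
        split = np.empty(len(self), dtype=object)
        split[self.train_idx] = "train"
        split[self.val_idx] = "val"
        df["split"] = split
        return df

    def save(self, csv_path, meta_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "seed": self.seed,
                "n": len(self),
                "eps_distribution": {"family": "shifted-exponential",
                                     "scale": EPS_SCALE, "shift": EPS_SHIFT},
                "width_range_m": [2 * A_MIN, 2 * A_MAX],
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, csv_path, seed: int = -1) -> "ShapeDatabase":
        df = pd.read_csv(csv_path)
        shapes = [
            Superquadric(*row[:9], label=lab)
            for row, lab in zip(df.iloc[:, :9].to_numpy(), df["label"])
        ]
        train_idx = np.flatnonzero(df["split"].to_numpy() == "train")
        val_idx = np.flatnonzero(df["split"].to_numpy() == "val")
        return cls(shapes, seed, train_idx, val_idx)


def _sample_eps(rng: np.random.Generator, size) -> np.ndarray:
    return rng.exponential(EPS_SCALE, size=size) + EPS_SHIFT


def sample_database(
    n: int,
    seed: int,
    class_mix: tuple = (1 / 3, 1 / 3, 1 / 3),
    train_fraction: float = 0.7,
) -> ShapeDatabase:
    """Sample a reproducible database of superquadric shapes.

    Classes (box-like, sphere-like, cylinder-like) appear in the given
    proportions.  Scales are uniform with widths in [0.02, 0.12] m; round
    edges use eps = 1 and squared edges draw eps from the shifted
    exponential; rotation angles are uniform over each class's canonical
    range (spin angles that symmetry makes redundant are left at 0).
    The split is 70/30 train/validation by default.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.floor(np.asarray(class_mix) / np.sum(class_mix) * n).astype(int)
    order = [BOX_LIKE, SPHERE_LIKE, CYLINDER_LIKE]
    for i in range(n - counts.sum()):
        counts[i % 3] += 1

    shapes: list[Superquadric] = []
    for label, m in zip(order, counts):
        if label == BOX_LIKE:
            A = rng.uniform(A_MIN, A_MAX, size=(m, 3))
            E = _sample_eps(rng, (m, 3))
            T = rng.uniform(-np.pi / 4, np.pi / 4, size=(m, 3))
        elif label == SPHERE_LIKE:
            base = rng.uniform(A_MIN / 0.85, A_MAX / 1.15, size=(m, 1))
            A = np.clip(base * rng.uniform(0.85, 1.15, size=(m, 3)), A_MIN, A_MAX)
            E = np.ones((m, 3))
            T = rng.uniform(-np.pi / 4, np.pi / 4, size=(m, 3))
        else:  # cylinder-like: round cross-section, elongated object z
            A3 = rng.uniform(0.035, A_MAX, size=m)
            A12 = rng.uniform(A_MIN, 0.65 * A3)
            A = np.column_stack([A12, A12, A3])
            E = np.column_stack([np.ones(m), np.ones(m), _sample_eps(rng, m)])
            T = np.column_stack(
                [
                    rng.uniform(-np.pi / 2, np.pi / 2, size=m),
                    rng.uniform(-np.pi / 2, np.pi / 2, size=m),
                    np.zeros(m),
                ]
            )
        for j in range(m):
            shapes.append(
                Superquadric(
                    A[j, 0], A[j, 1], A[j, 2],
                    E[j, 0], E[j, 1], E[j, 2],
                    T[j, 0], T[j, 1], T[j, 2],
                    label=label,
                )
            )

    perm = rng.permutation(n)
    shapes = [shapes[i] for i in perm]
    split_perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx = np.sort(split_perm[:n_train])
    val_idx = np.sort(split_perm[n_train:])
    return ShapeDatabase(shapes, seed, train_idx, val_idx)


def squared_edge_eps_samples(db: ShapeDatabase) -> np.ndarray:
    """All squared-edge exponent draws in a database (for distribution
    checks): the three box exponents and the cylinder cap exponent."""
    vals = []
    for s in db.shapes:
        if s.label == BOX_LIKE:
            vals.extend([s.eps1, s.eps2, s.eps3])
        elif s.label == CYLINDER_LIKE:
            vals.append(s.eps3)
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# Augmented tuning-curve stimulus enumeration
# ---------------------------------------------------------------------------

#: Default uniform size factors applied to all three axes.
DEFAULT_SIZES = (0.55, 0.70, 0.85, 1.0)

# Orientations a base shape's own rotational symmetry makes redundant:
# redundant orientation index -> kept representative index.
# Orientation indices follow ORIENTATION_NAMES:
#   0 vertical, 1 horizontal (rotated 90 deg about x), 2 tilted forward
#   45 deg, 3 tilted backward 45 deg.
_DUPLICATE_RULES = {
    # a sphere looks the same at every orientation
    "sphere": {1: 0, 2: 0, 3: 0},
    # a cube is invariant under 90-deg turns: horizontal == vertical and
    # backward tilt == forward tilt (exactly the same surface)
    "cube": {1: 0, 3: 2},
    # plates and cylinders: the backward tilt mirrors the forward tilt
    "plate": {3: 2},
    "cylinder": {3: 2},
}


def base_stimulus_shapes() -> dict:
    """The four Murata-style base shapes at full size, upright pose.

    The distinguished axis (cylinder long axis; plate normal) is the
    object z axis before the orientation rotation is applied.
    """
    return {
        "sphere": Superquadric(0.045, 0.045, 0.045, 1, 1, 1, label=SPHERE_LIKE),
        "cube": Superquadric(0.035, 0.035, 0.035, 0.05, 0.05, 0.05, label=BOX_LIKE),
        "plate": Superquadric(0.05, 0.05, 0.012, 0.05, 0.05, 0.05, label=PLATE_LIKE),
        "cylinder": Superquadric(0.015, 0.05, 0.015, 1, 0.05, 1, label=CYLINDER_LIKE),
    }


@dataclass
class StimulusSet:
    """Deduplicated stimuli for augmented tuning curves."""

    stimuli: list
    shape_names: list
    shape_id: np.ndarray
    size_id: np.ndarray
    orient_id: np.ndarray
    sizes: tuple = DEFAULT_SIZES
    #: (shape name, removed orientation id, kept orientation id) triples
    removed: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def orientation_angle(self) -> np.ndarray:
        """Rotation about the x axis, radians, per stimulus."""
        return np.array([ORIENTATION_ANGLES[i] for i in self.orient_id])


def _oriented(base: Superquadric, orient_id: int) -> Superquadric:
    return replace(base, theta1=ORIENTATION_ANGLES[orient_id], theta2=0.0, theta3=0.0)


def enumerate_stimuli(
    base_shapes: dict | None = None,
    sizes: tuple = DEFAULT_SIZES,
    orientations: tuple = ORIENTATION_NAMES,
) -> StimulusSet:
    """Enumerate the augmented-tuning stimulus grid with symmetry dedup.

    Every combination of base shape, size, and orientation is generated;
    orientations that a shape's own rotational symmetry makes redundant
    are removed (a sphere keeps 1 orientation, a cube 2, a plate and a
    cylinder 3 each).  The default 4 x 4 x 4 design yields 36 stimuli.
    """
    if base_shapes is None:
        base_shapes = base_stimulus_shapes()
    names = list(base_shapes)
    stimuli, shape_id, size_id, orient_id, removed = [], [], [], [], []
    for si, name in enumerate(names):
        rules = _DUPLICATE_RULES.get(name, {})
        kept = [o for o in range(len(orientations)) if o not in rules]
        for o, rep in rules.items():
            removed.append((name, o, rep))
        for zi, s in enumerate(sizes):
            for o in kept:
                stimuli.append(_oriented(base_shapes[name], o).scaled(s))
                shape_id.append(si)
                size_id.append(zi)
                orient_id.append(o)
    return StimulusSet(
        stimuli,
        names,
        np.asarray(shape_id),
        np.asarray(size_id),
        np.asarray(orient_id),
        tuple(sizes),
        removed,
    )


def stimulus_features(sset: StimulusSet) -> np.ndarray:
    """Per-stimulus feature vectors for cosine tuning over superquadric
    parameters.

    The stimuli rotate about a single axis, so the pose enters as a 2D
    direction vector (cos psi, sin psi) instead of the raw angle, which
    removes the angle discontinuity.  Feature order:
    [A1, A2, A3, eps1, eps2, eps3, cos psi, sin psi]  (8 values).
    """
    rows = []
    for sq, psi in zip(sset.stimuli, sset.orientation_angle):
        rows.append(
            [sq.A1, sq.A2, sq.A3, sq.eps1, sq.eps2, sq.eps3, np.cos(psi), np.sin(psi)]
        )
    return np.asarray(rows)
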