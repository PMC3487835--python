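"""Collective variables: superposition, the MSD metric, path CVs and
dihedral-similarity variables.

The path collective variables measure progress along (S) and distance
from (Z) a pre-defined sequence of P reference configurations:

    S(R) = [ sum_i (i-1) exp(-lambda D_i(R)) ]
           / [ (P-1) sum_i exp(-lambda D_i(R)) ]
    Z(R) = -(1/lambda) ln [ sum_i exp(-lambda D_i(R)) ]

where D_i is the mean-square deviation of the measured atoms after a
least-squares superposition onto frame i using the fit atoms, and lambda
controls the smoothness of S.  S is normalized to [0, 1]; the raw 1..P
convention is available via ``normalized=False``.

The dihedral-similarity variable N_theta scores n dihedrals against
reference values,

    N_theta = sum_i (1 + cos(theta_i - theta_i_ref)) / 2,

so it equals n when every dihedral sits at its reference and 0 when every
dihedral is half a turn away.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "Transform",
    "superpose",
    "msd_after_fit",
    "PathDefinition",
    "path_s",
    "path_z",
    "dihedral",
    "dihedrals",
    "DihedralParameterization",
    "n_theta",
]


@dataclasses.dataclass(frozen=True)
class Transform:
    """Rigid transform ``x -> x @ R.T + t`` (proper rotation, det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Sequence[int] | None = None,
) -> tuple[Transform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rigid transform over the fit atoms and the
    residual RMSD (angstrom).  Raises ValueError for fewer than three fit
    atoms or a collinear/degenerate selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = (
        np.arange(mobile.shape[0])
        if fit_selection is None
        else np.asarray(fit_selection, dtype=int)
    )
    if sel.size < 3:
        raise ValueError("need at least three fit atoms for superposition")
    a = mobile[sel]
    b = reference[sel]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    # collinearity: the second principal extent must be non-negligible
    sv_ref = np.linalg.svd(b0, compute_uv=False)
    if sv_ref[1] < 1e-8 * max(sv_ref[0], 1.0):
        raise ValueError("fit selection is collinear or degenerate")
    H = a0.T @ b0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = cb - ca @ R.T
    moved = a0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b0) ** 2, axis=1))))
    return Transform(R, t), rmsd


def msd_after_fit(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_selection: Sequence[int],
    measure_selection: Sequence[int],
    sort_measure_by_z: bool = False,
) -> float:
    """MSD (angstrom^2) of the measured atoms after fitting on the fit atoms.

    With ``sort_measure_by_z`` the measured atoms of both structures are
    relabeled by ascending z before the displacement is computed; this is
    the right metric for indistinguishable ions.
    """
    measure = np.asarray(measure_selection, dtype=int)
    if measure.size == 0:
        raise ValueError("measure_selection must not be empty")
    transform, _ = superpose(frame, reference, fit_selection)
    moved = transform.apply(np.asarray(frame, float)[measure])
    target = np.asarray(reference, float)[measure]
    if sort_measure_by_z:
        moved = moved[np.argsort(moved[:, 2], kind="stable")]
        target = target[np.argsort(target[:, 2], kind="stable")]
    return float(np.mean(np.sum((moved - target) ** 2, axis=1)))


@dataclasses.dataclass
class PathDefinition:
    """P ordered reference configurations plus the metric that compares to them.

    ``state_labels`` optionally maps occupancy-state codes to frame indices.
    """

    frames: list[np.ndarray]
    lam: float
    fit_selection: np.ndarray
    measure_selection: np.ndarray
    sort_measure_by_z: bool = False
    state_labels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if len(self.frames) < 2:
            raise ValueError("a path needs at least two frames")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        self.fit_selection = np.asarray(self.fit_selection, dtype=int)
        self.measure_selection = np.asarray(self.measure_selection, dtype=int)
        if self.fit_selection.size == 0 or self.measure_selection.size == 0:
            raise ValueError("fit and measure selections must be non-empty")
        n_atoms = self.frames[0].shape[0]
        for f in self.frames:
            if f.shape != self.frames[0].shape:
                raise ValueError("all frames must share one atom layout")
        for sel in (self.fit_selection, self.measure_selection):
            if sel.min() < 0 or sel.max() >= n_atoms:
                raise ValueError("selection indexes atoms outside the frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def distances(self, config: np.ndarray) -> np.ndarray:
        """MSD of ``config`` against every path frame (angstrom^2)."""
        return np.asarray(
            [
                msd_after_fit(
                    config,
                    f,
                    self.fit_selection,
                    self.measure_selection,
                    self.sort_measure_by_z,
                )
                for f in self.frames
            ]
        )

    def adjacent_msd(self) -> np.ndarray:
        """MSD between consecutive frames, used to sanity-check lambda."""
        return np.asarray(
            [
                msd_after_fit(
                    self.frames[i + 1],
                    self.frames[i],
                    self.fit_selection,
                    self.measure_selection,
                    self.sort_measure_by_z,
                )
                for i in range(self.n_frames - 1)
            ]
        )


def _path_weights(config: np.ndarray, path: PathDefinition) -> tuple[np.ndarray, float]:
    D = path.distances(config)
    dmin = float(D.min())
    if path.lam * dmin > 700.0:
        raise ValueError(
            "configuration is numerically infinitely far from every path frame; "
            "check lambda and the MSD metric/selections"
        )
    w = np.exp(-path.lam * (D - dmin))
    return w, dmin


def path_s(config: np.ndarray, path: PathDefinition, normalized: bool = True) -> float:
    """Progress along the path; in [0, 1] (default) or [1, P] (raw convention)."""
    w, _ = _path_weights(config, path)
    idx = np.arange(path.n_frames, dtype=float)
    s01 = float((idx * w).sum() / (w.sum() * (path.n_frames - 1)))
    return s01 if normalized else 1.0 + (path.n_frames - 1) * s01


def path_z(config: np.ndarray, path: PathDefinition) -> float:
    """Distance from the path (angstrom^2); bounded below by -(ln P)/lambda."""
    w, dmin = _path_weights(config, path)
    return dmin - math.log(float(w.sum())) / path.lam


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, range (-180, 180].

    cis = 0, trans = 180; positive for a clockwise rotation of p4 relative
    to p1 when looking along the p2 -> p3 axis.  Raises ValueError when
    three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3), 1e-30)
    if np.linalg.norm(n1) < 1e-9 * scale**2 or np.linalg.norm(n2) < 1e-9 * scale**2:
        raise ValueError("three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedrals(coords: np.ndarray, quadruples: np.ndarray) -> np.ndarray:
    """Dihedral angles (degrees) for an array of atom-index quadruples."""
    coords = np.asarray(coords, dtype=float)
    quadruples = np.asarray(quadruples, dtype=int)
    return np.asarray(
        [dihedral(*(coords[q] for q in quad)) for quad in quadruples]
    )


@dataclasses.dataclass
class DihedralParameterization:
    """n dihedrals (atom-index quadruples) with reference angles in degrees."""

    quadruples: np.ndarray
    reference_angles: np.ndarray

    def __post_init__(self) -> None:
        self.quadruples = np.asarray(self.quadruples, dtype=int)
        self.reference_angles = np.asarray(self.reference_angles, dtype=float)
        if self.quadruples.ndim != 2 or self.quadruples.shape[1] != 4:
            raise ValueError("quadruples must have shape (n, 4)")
        if self.reference_angles.shape != (self.quadruples.shape[0],):
            raise ValueError("one reference angle per quadruple required")

    @property
    def n(self) -> int:
        return self.quadruples.shape[0]


def n_theta(coords: np.ndarray, param: DihedralParameterization) -> float:
    """Dihedral similarity in [0, n]: n at reference, 0 at 180-degree offsets."""
    theta = dihedrals(coords, param.quadruples)
    delta = np.radians(theta - param.reference_angles)
    return float(np.sum(0.5 * (1.0 + np.cos(delta))))
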