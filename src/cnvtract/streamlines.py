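"""Streamline data model, TRK/TCK I/O, spline re-parameterisation and
shape feature vectors.

A *streamline* is an ordered polyline in millimetre (world/template)
space produced by tractography. Shape analysis requires every streamline
to be re-sampled to a fixed number of knot points at equal arc-length
spacing, given a deterministic head/tail orientation, centred at the
origin and flattened into a feature vector — the per-streamline
representation that the PCA shape basis in :mod:`cnvtract.shape`
consumes.

Conventions (frozen for reproducibility):

* all streamline coordinates are mm "world" space; voxel indices are
  0-based and the NIfTI affine maps the voxel *centre* to mm;
* the canonical orientation axis is anterior-positive ``(0, 1, 0)``,
  with ties broken by the z then x axes;
* feature vectors concatenate knot-major: ``(x1, y1, z1, x2, y2, z2, …)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Streamline",
    "Tractogram",
    "TractogramFormatError",
    "read_tractogram",
    "write_tractogram",
    "apply_affine",
    "reparameterize",
    "canonical_orient",
    "to_feature_vector",
    "DEFAULT_N_KNOTS",
    "ORIENTATION_AXIS_PRIORITY",
]

DEFAULT_N_KNOTS = 30

#: Axis priority for canonical orientation: anterior (+y), then superior
#: (+z), then left→right (+x).
ORIENTATION_AXIS_PRIORITY = (
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([1.0, 0.0, 0.0]),
)


class TractogramFormatError(ValueError):
    """Raised when a tractogram file cannot be parsed."""


@dataclass
class Streamline:
    """An ordered sequence of 3-D points (mm) with an optional bundle label.

    Invariants: at least two points, all coordinates finite, consecutive
    points non-identical.
    """

    points: np.ndarray
    bundle_label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"streamline points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("streamline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("streamline contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive streamline points must differ")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Polyline arc length in mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Tractogram:
    """A collection of streamlines sharing one coordinate space."""

    streamlines: list[Streamline] = field(default_factory=list)
    space_affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.space_affine, dtype=float)
        if A.shape != (4, 4):
            raise ValueError("space_affine must be 4x4")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValueError("space_affine must be invertible")
        self.space_affine = A

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _format_for(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        ext = os.path.splitext(str(path))[1].lower().lstrip(".")
        fmt = ext
    if fmt not in ("trk", "tck"):
        raise ValueError(f"unsupported tractogram format {fmt!r} (use 'trk' or 'tck')")
    return fmt


def _probe_offset(path: str | os.PathLike, fmt: str) -> int:
    """Best-effort byte offset of the first structural problem in a file."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(64)
            if fmt == "trk" and not head.startswith(b"TRACK"):
                return 0
            if fmt == "tck" and not head.startswith(b"mrtrix tracks"):
                return 0
            fh.seek(0, os.SEEK_END)
            return fh.tell()
    except OSError:
        return 0


def read_tractogram(path: str | os.PathLike, format: str | None = None,
                    subject_id: str | None = None) -> Tractogram:
    """Read a TRK or TCK tractogram into world (mm, RAS) coordinates.

    TRK voxel-order/affine header information is honoured: points are
    always returned in RAS mm regardless of on-disk voxel ordering.
    An empty file with a valid header yields a 0-streamline tractogram.
    """
    fmt = _format_for(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header/data errors
        off = _probe_offset(path, fmt)
        raise TractogramFormatError(
            f"{path}: malformed {fmt.upper()} stream (error near byte offset {off}): {exc}"
        ) from exc
    sls = [Streamline(np.asarray(p, dtype=float))
           for p in tf.tractogram.streamlines]
    affine = np.asarray(getattr(tf, "affine", np.eye(4)), dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        affine = np.eye(4)
    return Tractogram(streamlines=sls, space_affine=affine, subject_id=subject_id)


def write_tractogram(tractogram: Tractogram, path: str | os.PathLike,
                     format: str | None = None) -> None:
    """Write streamlines (world mm coordinates) to TRK or TCK."""
    fmt = _format_for(path, format)
    arrays = [s.points.astype(np.float32) for s in tractogram.streamlines]
    nt = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        nib.streamlines.save(nt, str(path))
        return
    # TRK stores points in a voxel-referenced frame; provide a header whose
    # voxel->mm map is the tractogram's space affine.
    header = nib.streamlines.trk.TrkFile.create_empty_header()
    header["voxel_to_ras"] = tractogram.space_affine.astype(np.float32)
    header["voxel_sizes"] = np.linalg.norm(
        tractogram.space_affine[:3, :3], axis=0).astype(np.float32)
    header["voxel_order"] = "".join(
        nib.orientations.aff2axcodes(tractogram.space_affine)).encode()
    if arrays:
        upper = np.ceil(np.max([a.max(axis=0) for a in arrays], axis=0)) + 10
        header["dimensions"] = np.maximum(upper, 10).astype(np.int16)
    nib.streamlines.save(nt, str(path), header=header)


def apply_affine(tractogram: Tractogram, A: np.ndarray) -> Tractogram:
    """Map every streamline point through the homogeneous transform ``A``.

    Used to move subject tractograms into a common template space so that
    positional/orientational variance is removed before shape analysis.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (4, 4) or abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("A must be an invertible 4x4 affine")
    R, t = A[:3, :3], A[:3, 3]
    new = [replace(s, points=s.points @ R.T + t) for s in tractogram.streamlines]
    return Tractogram(streamlines=new,
                      space_affine=A @ tractogram.space_affine,
                      subject_id=tractogram.subject_id)


def reparameterize(s: Streamline, n_knots: int = DEFAULT_N_KNOTS,
                   oversample: int = 10) -> Streamline:
    """Re-sample a streamline to ``n_knots`` points at equal arc length.

    A natural cubic spline is fitted through the input points
    (parameterised by cumulative chord length); arc length is measured on
    an ``oversample``-times denser polyline along the spline, and knots
    are placed at equal arc-length targets. Endpoints are preserved.
    Inputs with fewer than four points fall back to piecewise-linear
    interpolation (a cubic is not determined there).
    """
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    pts = s.points
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = chord.sum()
    if total <= 0.0:
        raise ValueError("cannot re-parameterise a zero-length streamline")
    t = np.concatenate(([0.0], np.cumsum(chord)))
    if len(pts) < 4:
        dense_t = np.linspace(0.0, t[-1], max(oversample * len(pts), n_knots * 4))
        dense = np.column_stack([np.interp(dense_t, t, pts[:, k]) for k in range(3)])
        evaluate = lambda u: np.column_stack(
            [np.interp(u, t, pts[:, k]) for k in range(3)])
    else:
        spline = CubicSpline(t, pts, bc_type="natural")
        dense_t = np.linspace(0.0, t[-1], oversample * len(pts))
        dense = spline(dense_t)
        evaluate = spline
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    targets = np.linspace(0.0, arc[-1], n_knots)
    u = np.interp(targets, arc, dense_t)
    new = np.asarray(evaluate(u), dtype=float)
    new[0], new[-1] = pts[0], pts[-1]  # endpoints exact
    return replace(s, points=new)


def canonical_orient(s: Streamline,
                     reference_axis: Sequence[float] = (0.0, 1.0, 0.0)) -> Streamline:
    """Flip a streamline so its head→tail displacement points along the axis.

    The streamline is reversed iff ``(last − first)·axis < 0``. If the
    displacement is orthogonal to the reference axis the tie is broken by
    the remaining axes of :data:`ORIENTATION_AXIS_PRIORITY`; a fully
    degenerate (closed-loop) displacement leaves the order unchanged.
    """
    axis = np.asarray(reference_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("reference_axis must be non-zero")
    axis = axis / norm
    disp = s.points[-1] - s.points[0]
    candidates = [axis] + [a for a in ORIENTATION_AXIS_PRIORITY
                           if abs(float(a @ axis)) < 1.0 - 1e-12]
    for a in candidates:
        d = float(disp @ a)
        if abs(d) > 1e-12:
            return replace(s, points=s.points[::-1].copy()) if d < 0 else s
    return s


def to_feature_vector(s: Streamline, n_knots: int = DEFAULT_N_KNOTS) -> np.ndarray:
    """Centre a re-parameterised streamline and flatten it knot-major.

    The centroid of the knot points is subtracted (translation
    invariance), then coordinates are concatenated as
    ``(x1, y1, z1, x2, y2, z2, …)`` giving a vector of length
    ``3 * n_knots``. The input must already be re-parameterised to
    ``n_knots`` points and canonically oriented.
    """
    if len(s) != n_knots:
        raise ValueError(f"streamline has {len(s)} points, expected n_knots={n_knots}")
    centred = s.points - s.points.mean(axis=0)
    return centred.reshape(-1).astype(float)


def streamlines_to_features(streamlines: Iterable[Streamline],
                            n_knots: int = DEFAULT_N_KNOTS,
                            reference_axis: Sequence[float] = (0.0, 1.0, 0.0),
                            ) -> np.ndarray:
    """Re-parameterise, orient and vectorise streamlines into an (n, 3k) array."""
    rows = [to_feature_vector(canonical_orient(reparameterize(s, n_knots),
                                               reference_axis), n_knots)
            for s in streamlines]
    if not rows:
        return np.empty((0, 3 * n_knots))
    return np.vstack(rows)
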