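"""Radial basis function displacement transforms.

Each displacement component is modelled as a first-order polynomial plus a
weighted sum of radially symmetric basis functions centred at the
landmarks:

    du_j(x) = P_j(x) + sum_i lambda_ij * f(d(x, x_i))

The coefficients solve the block design system

    [ 0   X ] [ a      ]   [ 0 ]
    [ X^T R ] [ lambda ] = [ D ]

where R holds basis values at landmark-landmark distances, X the landmark
coordinates (with a constant column) and D the landmark displacements; the
zero block imposes the side conditions sum_i lambda_ij = 0 and
sum_i lambda_ij x_i = 0.  The distance arguments are pluggable: Euclidean
distances give the classical unconstrained transform, mesh geodesic
distances give the constrained one.

Basis kinds: thin plate spline ``r^2 log r``; multiquadric
``sqrt(r^2+c^2)``; inverse multiquadric ``1/sqrt(r^2+c^2)``; Wendland's
compactly supported ``(1-r/c)^4 (4 r/c + 1)`` for ``r <= c``.  The shape
parameter is set as ``c = delta * r_max`` with ``r_max`` the maximum
extent of the object and ``delta`` useful in roughly [0.001, 0.5].
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .imagedomain import Domain, DomainError, bounding_box

__all__ = [
    "LandmarkSet",
    "RBFModel",
    "RBFFitError",
    "basis_eval",
    "compute_c",
    "fit_rbf",
    "evaluate_rbf",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
]

BASIS_KINDS = ("tps", "mq", "imq", "wendland")


class RBFFitError(ValueError):
    """Raised when the design system is rank deficient or inconsistent."""


@dataclasses.dataclass
class LandmarkSet:
    """Landmark centres with their displacement vectors.

    ``source``/``target`` optionally record the point pairs the
    displacements were derived from (displacement = source - target when
    the transform maps target space into source space).
    """

    centres: np.ndarray
    displacements: np.ndarray
    source: np.ndarray = None
    target: np.ndarray = None

    def __post_init__(self):
        self.centres = np.atleast_2d(np.asarray(self.centres, dtype=float))
        self.displacements = np.atleast_2d(
            np.asarray(self.displacements, dtype=float)
        )
        n, dim = self.centres.shape
        if self.displacements.shape != (n, dim):
            raise ValueError("displacements must match centres in shape")
        if n < dim + 1:
            raise ValueError(f"need at least dim+1={dim + 1} landmarks, got {n}")
        diff = self.centres[:, None, :] - self.centres[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        scale = max(np.ptp(self.centres, axis=0).max(), 1e-30)
        if d.min() < 1e-9 * scale:
            raise ValueError("duplicate (or near-duplicate) landmark centres")

    @property
    def n(self) -> int:
        return len(self.centres)

    @property
    def dim(self) -> int:
        return self.centres.shape[1]

    @classmethod
    def from_pairs(cls, target, source):
        """Build from (target, source) pairs; centres are the target
        points and displacements point from target into source space."""
        target = np.atleast_2d(np.asarray(target, dtype=float))
        source = np.atleast_2d(np.asarray(source, dtype=float))
        return cls(
            centres=target,
            displacements=source - target,
            source=source,
            target=target,
        )


@dataclasses.dataclass
class RBFModel:
    """Fitted RBF transform: basis kind and shape parameter, centres,
    basis coefficients ``lam`` (N x dim), first-order polynomial
    coefficients ``a`` ((dim+1) x dim, constant row first, acting on
    rescaled coordinates) and the affine coordinate rescale (lo, scale)."""

    kind: str
    c: float
    delta: float
    centres: np.ndarray
    lam: np.ndarray
    a: np.ndarray
    rescale: tuple

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "c": self.c,
            "delta": self.delta,
            "centres": self.centres.tolist(),
            "lambda": self.lam.tolist(),
            "a": self.a.tolist(),
            "rescale": [list(self.rescale[0]), list(self.rescale[1])],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RBFModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            c=float(d["c"]),
            delta=float(d["delta"]),
            centres=np.asarray(d["centres"], dtype=float),
            lam=np.asarray(d["lambda"], dtype=float),
            a=np.asarray(d["a"], dtype=float),
            rescale=(
                np.asarray(d["rescale"][0], dtype=float),
                np.asarray(d["rescale"][1], dtype=float),
            ),
        )


# -------------------------------------------------------------- basics ----

def basis_eval(kind: str, r, c: float = None):
    """Evaluate the radial basis ``kind`` at distances ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    if kind == "tps":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        return out
    if c is None or c <= 0:
        raise ValueError(f"basis {kind!r} requires a positive shape parameter c")
    if kind == "mq":
        return np.sqrt(r * r + c * c)
    if kind == "imq":
        return 1.0 / np.sqrt(r * r + c * c)
    if kind == "wendland":
        t = r / c
        return np.where(t <= 1.0, (1.0 - t) ** 4 * (4.0 * t + 1.0), 0.0)
    raise ValueError(f"unknown basis kind {kind!r}")


def compute_c(delta: float, domain: Domain) -> float:
    """Shape parameter ``c = delta * r_max`` from the domain extent."""
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    if not 0.001 <= delta <= 0.5:
        warnings.warn(
            f"delta={delta} outside the useful range [0.001, 0.5]", stacklevel=2
        )
    _, _, r_max = bounding_box(domain)
    if r_max == 0:
        raise DomainError("degenerate domain: r_max is zero")
    return delta * r_max


# ----------------------------------------------------------------- fit ----

def _design_matrix(centres_rs, R):
    n, dim = centres_rs.shape
    p = dim + 1
    P = np.concatenate([np.ones((n, 1)), centres_rs], axis=1)  # (n, p)
    M = np.zeros((n + p, n + p))
    M[:p, p:] = P.T
    M[p:, :p] = P
    M[p:, p:] = R
    return M


def fit_rbf(landmarks: LandmarkSet, pairwise_dist, kind: str, c: float = None,
            delta: float = np.nan) -> RBFModel:
    """Solve the design system for the basis and polynomial coefficients.

    ``pairwise_dist`` holds centre-centre distances (Euclidean or
    geodesic); it is symmetrised as ``(A + A.T)/2`` before basis
    evaluation since approximate geodesics break exact symmetry.
    Coordinates are affinely rescaled to the unit box before solving to
    reduce the condition number; the system is solved by SVD with a
    relative singular-value cutoff of 1e-12, shared across the ``dim``
    right-hand sides.
    """
    if kind not in BASIS_KINDS:
        raise ValueError(f"unknown basis kind {kind!r}")
    n, dim = landmarks.n, landmarks.dim
    Rd = np.asarray(pairwise_dist, dtype=float)
    if Rd.shape != (n, n):
        raise ValueError("pairwise_dist must be N x N")
    if np.any(np.abs(np.diag(Rd)) > 1e-9 * max(1.0, np.abs(Rd).max())):
        raise ValueError("pairwise_dist must have a zero diagonal")
    Rd = 0.5 * (Rd + Rd.T)
    np.fill_diagonal(Rd, 0.0)
    R = basis_eval(kind, Rd, c)

    lo = landmarks.centres.min(axis=0)
    scale = np.ptp(landmarks.centres, axis=0)
    scale[scale == 0] = 1.0
    centres_rs = (landmarks.centres - lo) / scale

    M = _design_matrix(centres_rs, R)
    p = dim + 1
    rhs = np.zeros((n + p, dim))
    rhs[p:] = landmarks.displacements

    U, s, Vt = np.linalg.svd(M)
    cutoff = 1e-12 * s.max()
    keep = s > cutoff
    if not keep.all():
        raise RBFFitError(
            f"design matrix rank deficient after cutoff: rank {keep.sum()} of "
            f"{len(s)} (collinear/coplanar centres?)"
        )
    sol = Vt.T @ ((U.T @ rhs) / s[:, None])
    a = sol[:p]
    lam = sol[p:]
    return RBFModel(
        kind=kind,
        c=float(c) if c is not None else 0.0,
        delta=float(delta),
        centres=landmarks.centres.copy(),
        lam=lam,
        a=a,
        rescale=(lo, scale),
    )


def evaluate_rbf(model: RBFModel, points, dist_to_centres) -> np.ndarray:
    """Displacements at ``points`` given their distances to the centres.

    The polynomial term uses the points' coordinates (rescaled as at fit
    time); the basis term uses the supplied distance rows, whose columns
    must follow the model's centre order.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dist = np.atleast_2d(np.asarray(dist_to_centres, dtype=float))
    if dist.shape != (len(points), len(model.centres)):
        raise ValueError("dist_to_centres must be M x N in model centre order")
    if np.any(dist < 0):
        raise ValueError("distances must be nonnegative")
    lo, scale = model.rescale
    pts_rs = (points - lo) / scale
    P = np.concatenate([np.ones((len(points), 1)), pts_rs], axis=1)
    f = basis_eval(model.kind, dist, model.c if model.c > 0 else None)
    return P @ model.a + f @ model.lam


# ---------------------------------------------------------- landmark IO ----

def write_landmarks_tsv(path, target, source) -> None:
    """Landmark pair TSV: header, then target coords followed by source
    coords per row (``tx ty [tz] sx sy [sz]``), world units."""
    target = np.atleast_2d(np.asarray(target, dtype=float))
    source = np.atleast_2d(np.asarray(source, dtype=float))
    dim = target.shape[1]
    axes = "xyz"[:dim]
    header = "\t".join([f"t{a}" for a in axes] + [f"s{a}" for a in axes])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for t, s in zip(target, source):
            fh.write("\t".join(f"{v:.17g}" for v in np.concatenate([t, s])) + "\n")


def read_landmarks_tsv(path):
    """Read a landmark pair TSV; returns (target, source) arrays."""
    with open(path) as fh:
        header = fh.readline().split()
        dim = len(header) // 2
        rows = [[float(v) for v in line.split()] for line in fh if line.strip()]
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 * dim:
        raise ValueError("malformed landmark TSV")
    return arr[:, :dim], arr[:, dim:]
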