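"""Reference sphere discretization and prescribed spreading kinematics.

The cell membrane is modeled as the surface of a sphere of radius ``r0`` in
its reference (suspended) configuration.  Axisymmetry reduces the surface to
a one-dimensional meridian parameterized by the polar angle ``theta`` in
``[0, pi]``; ``theta = pi`` is the pole facing the glass slide.

The mechanical deformation during adhesion is not solved here.  Instead, a
prescribed, volume-conserving family of spread shapes — a spherical cap
sitting on a flat contact disc — stands in for the full finite-element
mechanics.  The contact-disc radius follows a piecewise-linear schedule
through the three experimental stages (attachment, translocation, diffusion),
and material points are mapped from the reference sphere to the current shape
by matching cumulative area fractions.  Because the chemistry is only one-way
coupled to the mechanics, any kinematics that reproduces the observed contact
areas and timings drives the transport problem equivalently.

Units: lengths in µm, areas in µm², volumes in µm³, time in s.  The slide is
the plane ``y = 0`` with upward normal ``e_2``; the cell sits above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSphereMesh",
    "StagePlan",
    "CapGeometry",
    "KinematicsFrame",
    "CapKinematics",
    "build_meridian_mesh",
    "contact_radius_schedule",
    "cap_shape",
    "map_reference_to_current",
    "gap_function",
    "hsm_check",
]


@dataclass(frozen=True)
class ReferenceSphereMesh:
    """Meridian discretization of the reference membrane sphere.

    Attributes
    ----------
    r0 : float
        Reference cell radius (µm).
    theta : ndarray
        Strictly increasing polar angles in ``[0, pi]``; ``theta = pi`` is
        the pole facing the slide.
    weights : ndarray
        Reference area (µm²) of the spherical zone bounded by the Voronoi
        midpoints around each node; sums exactly to ``4 pi r0**2``.
    segments : ndarray of shape (n-1, 2)
        Adjacent-node connectivity along the meridian.
    """

    r0: float
    theta: np.ndarray
    weights: np.ndarray
    segments: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.theta.size

    @property
    def total_area(self) -> float:
        """Total reference membrane area (µm²)."""
        return float(self.weights.sum())

    @property
    def area_fraction(self) -> np.ndarray:
        """Cumulative reference-area fraction measured from the slide pole.

        A node at polar angle ``theta`` bounds the fraction
        ``(1 + cos(theta)) / 2`` of the sphere between itself and the pole
        ``theta = pi``.
        """
        return (1.0 + np.cos(self.theta)) / 2.0


@dataclass(frozen=True)
class StagePlan:
    """Timing of the three experimental stages and their time steps.

    Defaults follow the in vitro protocol: attachment 0–300 s, mechanical
    translocation 300–600 s, diffusion-dominated relaxation 600–7200 s, with
    mechanical steps of 0.5 / 0.1 / 0.05 s respectively and a chemo
    sub-incrementation factor applied within each mechanical step.
    """

    t_attach: float = 300.0
    t_transloc: float = 600.0
    t_end: float = 7200.0
    dt_stage: tuple[float, float, float] = (0.5, 0.1, 0.05)
    substeps: int | tuple[int, int, int] = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.t_attach < self.t_transloc < self.t_end):
            raise ValueError("stage boundaries must satisfy 0 < t_attach < t_transloc < t_end")
        if any(dt <= 0.0 for dt in self.dt_stage):
            raise ValueError("all stage time steps must be positive")
        if any(s < 1 for s in self.substeps_by_stage):
            raise ValueError("substeps must be positive integers")

    @property
    def substeps_by_stage(self) -> tuple[int, int, int]:
        """Chemo sub-incrementation factor per stage.

        A single integer applies to all three stages; a triple sets them
        individually (the diffusion stage can use a reduced factor because
        its kinematics is frozen).
        """
        if isinstance(self.substeps, int):
            return (self.substeps, self.substeps, self.substeps)
        return tuple(self.substeps)

    def stage_of(self, t: float) -> int:
        """Stage index (0, 1, 2) containing time ``t`` (right-open intervals)."""
        if t < self.t_attach:
            return 0
        if t < self.t_transloc:
            return 1
        return 2


@dataclass(frozen=True)
class CapGeometry:
    """A spherical cap of base radius ``a``, height ``h`` and sphere radius ``R_s``.

    The enclosed volume is ``V = pi h (3 a**2 + h**2) / 6``; for ``a > 0`` the
    cap's sphere radius is ``R_s = (a**2 + h**2) / (2 h)``.  ``a = 0`` is the
    degenerate full sphere (``h = 2 R_s``).
    """

    a: float
    h: float
    R_s: float
    V: float

    @property
    def disc_area(self) -> float:
        """Area of the flat contact disc, ``pi a**2`` (µm²)."""
        return np.pi * self.a**2

    @property
    def lateral_area(self) -> float:
        """Curved (cap) surface area, ``2 pi R_s h`` (µm²)."""
        return 2.0 * np.pi * self.R_s * self.h

    @property
    def total_area(self) -> float:
        """Current total membrane area: contact disc plus spherical cap."""
        return self.disc_area + self.lateral_area


@dataclass(frozen=True)
class KinematicsFrame:
    """Per-node snapshot of the current membrane configuration at time ``t``.

    ``rho`` and ``y`` are the meridian coordinates (axial distance and height
    above the slide) of each material node; ``g_N = y`` is the contact gap and
    ``lambda_a`` the areal stretch (current area per unit reference area).
    """

    t: float
    rho: np.ndarray
    y: np.ndarray
    g_N: np.ndarray
    lambda_a: np.ndarray
    cap: CapGeometry = field(repr=False, default=None)
    contact: np.ndarray = field(repr=False, default=None)


def build_meridian_mesh(r0: float, n_nodes: int) -> ReferenceSphereMesh:
    """Discretize the reference sphere meridian with uniformly spaced angles.

    Nodal weights are the exact areas of the spherical zones bounded by the
    midpoints between adjacent nodes (Voronoi intervals on the meridian), so
    they partition the sphere area exactly for any resolution.

    Parameters
    ----------
    r0 : float
        Sphere radius (µm), must be positive.
    n_nodes : int
        Number of meridian nodes including both poles, at least 3.
    """
    if r0 <= 0.0:
        raise ValueError(f"r0 must be positive, got {r0}")
    if n_nodes < 3:
        raise ValueError(f"need at least 3 meridian nodes, got {n_nodes}")
    theta = np.linspace(0.0, np.pi, n_nodes)
    # Zone boundaries: the poles plus midpoints between adjacent nodes.
    edges = np.concatenate(([0.0], 0.5 * (theta[:-1] + theta[1:]), [np.pi]))
    weights = 2.0 * np.pi * r0**2 * (np.cos(edges[:-1]) - np.cos(edges[1:]))
    segments = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    return ReferenceSphereMesh(r0=float(r0), theta=theta, weights=weights, segments=segments)


def contact_radius_schedule(
    t: float, plan: StagePlan, a_attach: float = 3.35, a_final: float = 19.8
) -> float:
    """Prescribed contact-disc radius (µm) at time ``t``.

    Piecewise linear and continuous: zero at first touch, ``a_attach`` at the
    end of the attachment stage, ``a_final`` at the end of translocation, and
    constant afterwards.  The defaults are the radii of the simulated contact
    discs at the two stage ends (diameters 6.7 µm and 39.6 µm).
    """
    if t < 0.0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if t <= plan.t_attach:
        return a_attach * t / plan.t_attach
    if t <= plan.t_transloc:
        frac = (t - plan.t_attach) / (plan.t_transloc - plan.t_attach)
        return a_attach + (a_final - a_attach) * frac
    return a_final


def cap_shape(a: float, V: float) -> CapGeometry:
    """Spherical cap of base radius ``a`` enclosing volume ``V``.

    The cap height solves the monotone cubic ``h**3 + 3 a**2 h - 6 V / pi = 0``
    (unique positive root, obtained in closed form by Cardano's formula for a
    depressed cubic with nonnegative linear coefficient).
    """
    if a < 0.0:
        raise ValueError(f"contact radius must be nonnegative, got {a}")
    if V <= 0.0:
        raise ValueError(f"volume must be positive, got {V}")
    p = 3.0 * a**2
    q = 6.0 * V / np.pi
    # h^3 + p h - q = 0 with p >= 0, q > 0: discriminant positive, one real root.
    disc = np.sqrt((q / 2.0) ** 2 + (p / 3.0) ** 3)
    h = np.cbrt(q / 2.0 + disc) + np.cbrt(q / 2.0 - disc)
    if not np.isfinite(h) or h <= 0.0:
        raise ArithmeticError(f"cap-height solve failed for a={a}, V={V}")
    # One Newton polish for the analytic root (guards cancellation at large a).
    h -= (h**3 + p * h - q) / (3.0 * h**2 + p)
    R_s = (a**2 + h**2) / (2.0 * h)
    return CapGeometry(a=float(a), h=float(h), R_s=float(R_s), V=float(V))


def map_reference_to_current(
    mesh: ReferenceSphereMesh, cap: CapGeometry, t: float
) -> KinematicsFrame:
    """Place material nodes on the current cap shape by area-fraction matching.

    The reference node with cumulative reference-area fraction ``f`` (measured
    from the slide-facing pole) is placed at the point of the current surface
    — contact disc first, then the spherical cap traversed upward — with the
    same cumulative current-area fraction.  The map is monotone, so meridian
    ordering is preserved.  The areal stretch is spatially uniform and equals
    the ratio of current to reference total area.
    """
    f = mesh.area_fraction[::-1]  # ascending from the slide pole ...
    A_cur = cap.total_area
    f_disc = cap.disc_area / A_cur
    cum = f * A_cur  # cumulative current area assigned to each node

    on_disc = f <= f_disc + 1e-15
    rho = np.empty_like(f)
    y = np.empty_like(f)
    # Contact disc: radial position from enclosed area; gap exactly zero.
    rho[on_disc] = np.sqrt(np.maximum(cum[on_disc], 0.0) / np.pi)
    y[on_disc] = 0.0
    # Spherical cap: the zone area above the rim grows linearly with height.
    y_c = cap.h - cap.R_s  # height of the cap-sphere center
    yy = (cum[~on_disc] - cap.disc_area) / (2.0 * np.pi * cap.R_s)
    yy = np.minimum(yy, cap.h)
    rho[~on_disc] = np.sqrt(np.maximum(cap.R_s**2 - (yy - y_c) ** 2, 0.0))
    y[~on_disc] = yy

    # Restore the mesh's native node order (theta ascending, apex first).
    rho, y, on_disc = rho[::-1].copy(), y[::-1].copy(), on_disc[::-1].copy()
    lam = np.full(mesh.n_nodes, A_cur / mesh.total_area)
    return KinematicsFrame(
        t=float(t), rho=rho, y=y, g_N=y.copy(), lambda_a=lam, cap=cap, contact=on_disc
    )


def gap_function(frame: KinematicsFrame) -> np.ndarray:
    """Per-node gap to the slide plane ``y = 0``: simply the node height.

    Raises if any node lies below the slide (interpenetration), which the
    cap construction excludes.
    """
    g = frame.y
    if np.any(g < 0.0):
        raise ValueError("membrane interpenetrates the slide: negative node height")
    return g.copy()


def hsm_check(
    g_N: np.ndarray, p_N: np.ndarray, tol: float = 1e-10, tol_c: float = 1e-8
) -> np.ndarray:
    """Indices of nodes violating the frictionless-contact complementarity triple.

    The Hertz–Signorini–Moreau conditions require ``g_N >= 0`` (no
    penetration), ``p_N <= 0`` (contact pressure only pushes), and
    ``p_N * g_N = 0`` (no traction at a distance), the product checked
    against ``tol_c``.
    """
    g_N = np.asarray(g_N, dtype=float)
    p_N = np.asarray(p_N, dtype=float)
    if g_N.shape != p_N.shape:
        raise ValueError(f"gap and pressure arrays differ in shape: {g_N.shape} vs {p_N.shape}")
    bad = (g_N < -tol) | (p_N > tol) | (np.abs(p_N * g_N) > tol_c)
    return np.nonzero(bad)[0]


class CapKinematics:
    """Default kinematics provider: volume-conserving spherical-cap family.

    Callable mapping a time to a :class:`KinematicsFrame` on a given mesh.
    The enclosed volume is held at the reference-sphere volume
    ``(4/3) pi r0**3`` at every instant, and the contact radius follows
    :func:`contact_radius_schedule`.  Any object with the same call signature
    (e.g. wrapping precomputed finite-element shapes) can be substituted.
    """

    def __init__(
        self,
        mesh: ReferenceSphereMesh,
        plan: StagePlan,
        a_attach: float = 3.35,
        a_final: float = 19.8,
    ) -> None:
        self.mesh = mesh
        self.plan = plan
        self.a_attach = a_attach
        self.a_final = a_final
        self.volume = 4.0 / 3.0 * np.pi * mesh.r0**3

    def contact_radius(self, t: float) -> float:
        return contact_radius_schedule(t, self.plan, self.a_attach, self.a_final)

    def __call__(self, t: float) -> KinematicsFrame:
        cap = cap_shape(self.contact_radius(t), self.volume)
        return map_reference_to_current(self.mesh, cap, t)
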