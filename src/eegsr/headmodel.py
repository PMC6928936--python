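"""Three-concentric-shell volume conductor and its dipole forward solution.

The head is modeled as three concentric spheres (brain, skull, scalp) with
relative radii (0.87, 0.92, 1.0) and relative conductivities (1, 0.0125, 1).
For spherical geometry the boundary-value problem has a classical series
solution: expand the dipole's free-medium potential in Legendre harmonics and
propagate each degree through the shells with the continuity conditions
(potential and radial current continuous at interfaces, zero radial current
at the scalp-air boundary). The series is exact on spheres, deterministic,
and reduces to the textbook homogeneous-sphere closed form when all three
conductivities coincide -- which is how it is validated.

All positions are in scalp-normalized units (scalp radius = 1); the physical
scalp radius in mm converts source-space distances to mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadModel",
    "DipoleSource",
    "three_shell_potential",
    "homogeneous_sphere_potential",
    "compute_leadfield",
    "shell_surface_coefficients",
]


@dataclass
class HeadModel:
    """Concentric brain/skull/scalp shells.

    ``shell_radii`` are relative to the scalp (last radius must be 1.0);
    ``conductivities`` are relative; ``scalp_radius_mm`` sets the physical
    scale used for metric distances (localization error, grid spacing).
    """

    shell_radii: tuple = (0.87, 0.92, 1.0)
    conductivities: tuple = (1.0, 0.0125, 1.0)
    scalp_radius_mm: float = 100.0

    def __post_init__(self):
        r = tuple(float(x) for x in self.shell_radii)
        if len(r) != 3 or not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be three strictly increasing values")
        if abs(r[2] - 1.0) > 1e-12:
            raise ValueError("outermost (scalp) radius must be 1.0")
        s = tuple(float(x) for x in self.conductivities)
        if len(s) != 3 or any(x <= 0 for x in s):
            raise ValueError("need three positive conductivities")
        if self.scalp_radius_mm <= 0:
            raise ValueError("scalp_radius_mm must be positive")
        self.shell_radii = r
        self.conductivities = s

    @property
    def brain_radius(self) -> float:
        return self.shell_radii[0]

    @property
    def brain_radius_mm(self) -> float:
        return self.shell_radii[0] * self.scalp_radius_mm


@dataclass
class DipoleSource:
    """Current dipole inside the brain shell.

    ``position`` is scalp-normalized, strictly inside the brain shell;
    ``orientation`` is a unit moment direction; ``waveform`` is the moment
    magnitude over time (arbitrary amplitude units) at the trial sampling
    rate.
    """

    position: np.ndarray
    orientation: np.ndarray
    waveform: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        n = np.linalg.norm(ori)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = ori / n
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()

    def validate_inside(self, head: HeadModel) -> None:
        if np.linalg.norm(self.position) >= head.brain_radius:
            raise ValueError(
                f"dipole at radius {np.linalg.norm(self.position):.3f} is not "
                f"strictly inside the brain shell (radius {head.brain_radius})"
            )


def shell_surface_coefficients(n_max: int, head: HeadModel) -> np.ndarray:
    """Scalp-surface radial coefficients c_n, degrees 0..n_max.

    For each harmonic degree n the dipole's free-medium potential contributes
    a term ~ r^-(n+1) inside the brain; the shells replace its value at the
    scalp surface by c_n. Index 0 is unused (a dipole has no monopole term).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    r1, r2, R = head.shell_radii
    s1, s2, s3 = head.conductivities
    n = np.arange(1, n_max + 1, dtype=float)
    # unknowns per degree: A1, A2, B2, A3, B3
    A = np.zeros((n_max, 5, 5))
    rhs = np.zeros((n_max, 5))
    A[:, 0, 0] = r1 ** n
    A[:, 0, 1] = -(r1 ** n)
    A[:, 0, 2] = -(r1 ** -(n + 1))
    rhs[:, 0] = -(r1 ** -(n + 1))
    A[:, 1, 0] = s1 * n * r1 ** (n - 1)
    A[:, 1, 1] = -s2 * n * r1 ** (n - 1)
    A[:, 1, 2] = s2 * (n + 1) * r1 ** -(n + 2)
    rhs[:, 1] = s1 * (n + 1) * r1 ** -(n + 2)
    A[:, 2, 1] = r2 ** n
    A[:, 2, 2] = r2 ** -(n + 1)
    A[:, 2, 3] = -(r2 ** n)
    A[:, 2, 4] = -(r2 ** -(n + 1))
    A[:, 3, 1] = s2 * n * r2 ** (n - 1)
    A[:, 3, 2] = -s2 * (n + 1) * r2 ** -(n + 2)
    A[:, 3, 3] = -s3 * n * r2 ** (n - 1)
    A[:, 3, 4] = s3 * (n + 1) * r2 ** -(n + 2)
    A[:, 4, 3] = n * R ** (n - 1)
    A[:, 4, 4] = -(n + 1) * R ** -(n + 2)
    x = np.linalg.solve(A, rhs[..., None])[..., 0]
    c = np.zeros(n_max + 1)
    c[1:] = x[:, 3] * R ** n + x[:, 4] * R ** -(n + 1)
    return c


def _gain_series(voxels, sensors, head: HeadModel, n_terms: int):
    """Potentials of unit x/y/z dipoles at each voxel, shape (V, S, 3).

    Vectorized Legendre recurrence over all voxel-sensor pairs; output is not
    average-referenced.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    sensors = np.asarray(sensors, dtype=float)
    rhat = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    b = np.linalg.norm(voxels, axis=1)  # (V,)
    if np.any(b >= head.brain_radius):
        raise ValueError("all source positions must be strictly inside the brain shell")
    # central dipoles: only the n=1 term survives (b^(n-1) -> 0^(n-1));
    # its value is independent of the unit vector chosen here.
    safe = b > 1e-12
    r0 = np.where(safe[:, None], voxels / np.where(safe, b, 1.0)[:, None],
                  np.array([0.0, 0.0, 1.0]))
    cs = shell_surface_coefficients(n_terms, head)
    c = r0 @ rhat.T  # (V, S) cos(angle)
    P_nm1 = np.ones_like(c)
    P_n = c.copy()
    Pd_n = np.ones_like(c)
    Pd_nm1 = np.zeros_like(c)
    g_r = np.zeros_like(c)       # multiplies (q . r0hat)
    g_t = np.zeros((*c.shape, 3))  # multiplies q via (rhat - c r0hat)
    bpow = np.ones_like(b)       # b^(n-1)
    for n in range(1, n_terms + 1):
        w = bpow[:, None] * cs[n]
        g_r += w * n * P_n
        g_t += (w * Pd_n)[..., None] * (rhat[None, :, :] - c[..., None] * r0[:, None, :])
        bpow = bpow * b
        P_np1 = ((2 * n + 1) * c * P_n - n * P_nm1) / (n + 1)
        Pd_np1 = Pd_nm1 + (2 * n + 1) * P_n
        P_nm1, P_n = P_n, P_np1
        Pd_nm1, Pd_n = Pd_n, Pd_np1
    gain = g_r[..., None] * r0[:, None, :] + g_t
    gain /= 4 * np.pi * head.conductivities[0]
    return gain


def three_shell_potential(dipole, montage, head: HeadModel,
                          n_terms: int = 100) -> np.ndarray:
    """Average-referenced scalp potentials of a unit-magnitude dipole moment.

    Returns one potential per montage sensor for the dipole's position and
    orientation at unit moment magnitude; scale by the waveform for a time
    series. Linear in the dipole moment.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    dip = dipole if isinstance(dipole, DipoleSource) else DipoleSource(*dipole)
    dip.validate_inside(head)
    gain = _gain_series(dip.position[None, :], montage.positions, head, n_terms)[0]
    v = gain @ dip.orientation
    return v - v.mean()


def homogeneous_sphere_potential(position, moment, sensors, radius: float = 1.0,
                                 sigma: float = 1.0) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Textbook result for a current dipole inside a uniformly conducting sphere
    with insulating exterior, obtained by summing the Legendre series in
    closed form. Average-referenced to match :func:`three_shell_potential`.
    Independent of the shell series solver; used as its oracle.
    """
    position = np.asarray(position, dtype=float).reshape(3)
    moment = np.asarray(moment, dtype=float).reshape(3)
    sensors = np.asarray(sensors, dtype=float)
    b = np.linalg.norm(position)
    if b >= radius:
        raise ValueError("dipole must be inside the sphere")
    rhat = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    if b < 1e-12:
        v = 3.0 * (rhat @ moment) / (4 * np.pi * sigma * radius**2)
        return v - v.mean()
    f = b / radius
    r0 = position / b
    c = rhat @ r0
    qr = moment @ r0
    qt = rhat @ moment - c * qr  # q . (rhat - c*r0hat)
    s = np.sqrt(1 - 2 * f * c + f * f)
    term_r = 2 * (c - f) / s**3 + (1 / f) * (1 / s - 1)
    term_t = 2 / s**3 + (1 + s) / (s * (1 - f * c + s))
    v = (qr * term_r + qt * term_t) / (4 * np.pi * sigma * radius**2)
    return v - v.mean()


def compute_leadfield(voxels, montage, head: HeadModel,
                      n_terms: int = 100) -> np.ndarray:
    """Gain matrix: average-referenced sensor potentials of unit dipoles.

    Parameters
    ----------
    voxels : ndarray, shape (V, 3)
        Source positions in scalp-normalized units, inside the brain shell.

    Returns
    -------
    ndarray, shape (n_sensors, V, 3)
        Potential at each sensor for a unit dipole along x/y/z at each voxel.
    """
    gain = _gain_series(voxels, montage.positions, head, n_terms)  # (V, S, 3)
    gain = np.moveaxis(gain, 0, 1)  # (S, V, 3)
    return gain - gain.mean(axis=0, keepdims=True)
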