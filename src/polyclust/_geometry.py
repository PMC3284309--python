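"""Internal 3D geometry helpers: angles, rotations, chain construction.

Angle conventions used throughout the package:

* *deflection angle* between consecutive bonds = angle between successive
  bond direction vectors (0 = collinear/extended chain, pi = full reversal).
* *dihedral angle* of four consecutive particles = signed torsion in
  (-pi, pi], 0 for the eclipsed (cis, planar same-side) arrangement.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize the zero vector")
    return v / n


def rotate_about_axis(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` by ``angle`` about unit vector ``axis``."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def deflection_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Deflection between bonds (p0->p1) and (p1->p2); 0 means collinear."""
    u = unit(p1 - p0)
    v = unit(p2 - p1)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral of four points, in (-pi, pi], 0 = eclipsed."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    x = float(np.dot(m, n))
    y = float(np.dot(np.cross(m, n), unit(b2)))
    return float(np.arctan2(y, x))


def transported_frame_chain(n_links: int, link_length: float, phi: float,
                            theta: float) -> np.ndarray:
    """Build a chain with uniform joint angles via a parallel-transported frame.

    Particle 0 sits at the origin and bond 1 points along the lab +z axis.
    Each subsequent bond direction is obtained from the previous one by a
    deflection ``theta`` toward a parallel-transported normal, followed by a
    rotation ``phi`` about the previous bond direction.  ``theta = 0`` gives
    the fully extended chain regardless of ``phi``.
    """
    pos = np.zeros((n_links + 1, 3))
    t = np.array([0.0, 0.0, 1.0])
    nvec = np.array([1.0, 0.0, 0.0])
    pos[1] = pos[0] + link_length * t
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    for i in range(1, n_links):
        b = np.cross(t, nvec)
        t_new = ct * t + st * (cp * nvec + sp * b)
        t_new = unit(t_new)
        # parallel transport the normal by the minimal rotation t -> t_new
        axis = np.cross(t, t_new)
        s = np.linalg.norm(axis)
        if s > 1e-12:
            ang = np.arctan2(s, np.dot(t, t_new))
            nvec = rotate_about_axis(nvec, axis / s, ang)
            nvec = unit(nvec - np.dot(nvec, t_new) * t_new)
        t = t_new
        pos[i + 1] = pos[i] + link_length * t
    return pos


def chain_from_internal(link_length: float, deflections: np.ndarray,
                        torsions: np.ndarray) -> np.ndarray:
    """Build a chain from internal coordinates (NeRF-style placement).

    Parameters
    ----------
    link_length : float
        Common bond length.
    deflections : array, shape (n_bonds - 1,)
        Deflection angle at each internal joint (between bonds i and i+1).
    torsions : array, shape (n_bonds - 2,)
        Dihedral angle of each quadruple of consecutive particles, in the
        convention of :func:`dihedral_angle`.
    """
    deflections = np.asarray(deflections, dtype=np.float64)
    torsions = np.asarray(torsions, dtype=np.float64)
    n_bonds = len(deflections) + 1
    if len(torsions) != n_bonds - 2:
        raise ValueError("need exactly n_bonds - 2 torsions")
    pos = np.zeros((n_bonds + 1, 3))
    pos[1] = [0.0, 0.0, link_length]
    if n_bonds == 1:
        return pos
    # second bond: deflect in the xz-plane (reference normal = +y)
    a0 = deflections[0]
    d = np.array([np.sin(a0), 0.0, np.cos(a0)])
    pos[2] = pos[1] + link_length * d
    for i in range(2, n_bonds):
        u_prev = unit(pos[i] - pos[i - 1])
        u_pp = unit(pos[i - 1] - pos[i - 2])
        nvec = np.cross(u_pp, u_prev)
        s = np.linalg.norm(nvec)
        if s < 1e-12:  # collinear previous bonds: torsion reference arbitrary
            nvec = np.cross(u_prev, np.array([1.0, 0.0, 0.0]))
            if np.linalg.norm(nvec) < 1e-12:
                nvec = np.cross(u_prev, np.array([0.0, 1.0, 0.0]))
            nvec = unit(nvec)
        else:
            nvec = nvec / s
        mvec = np.cross(nvec, u_prev)
        a, tau = deflections[i - 1], torsions[i - 2]
        d = (np.cos(a) * u_prev
             + np.sin(a) * (np.cos(tau) * mvec + np.sin(tau) * nvec))
        pos[i + 1] = pos[i] + link_length * unit(d)
    return pos
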