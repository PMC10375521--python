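"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the overlap oracle is a
point-sampling membership test built on the closed-form signed distance of a
point to a cylinder, and the quadrature oracle is a dense Simpson integration
of the cylinder form-factor integrand.
"""

import numpy as np
from numba import njit
from scipy import special
from scipy.integrate import simpson


@njit(cache=True)
def signed_distance_point_cylinder(x, y, z, p, a, hL, R):
    """Signed distance of a point to a closed cylinder (negative inside)."""
    dx, dy, dz = x - p[0], y - p[1], z - p[2]
    az = dx * a[0] + dy * a[1] + dz * a[2]
    r2 = dx * dx + dy * dy + dz * dz - az * az
    r = np.sqrt(max(r2, 0.0))
    dax = abs(az) - hL
    drad = r - R
    if dax <= 0.0 and drad <= 0.0:
        return max(dax, drad)
    if dax > 0.0 and drad > 0.0:
        return np.sqrt(dax * dax + drad * drad)
    return max(dax, drad)


@njit(cache=True)
def min_signed_distance_sampled(pa, aa, pb, ab, hL, R, npts, seed):
    """Min over sampled points of cylinder A (volume, lateral surface, caps)
    of the signed distance to cylinder B.

    Negative => the cylinders certainly overlap; a positive value bounds the
    separation from below up to the sampling resolution.
    """
    np.random.seed(seed)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(aa[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.empty(3)
    u[0] = aa[1] * ref[2] - aa[2] * ref[1]
    u[1] = aa[2] * ref[0] - aa[0] * ref[2]
    u[2] = aa[0] * ref[1] - aa[1] * ref[0]
    u /= np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    w = np.empty(3)
    w[0] = aa[1] * u[2] - aa[2] * u[1]
    w[1] = aa[2] * u[0] - aa[0] * u[2]
    w[2] = aa[0] * u[1] - aa[1] * u[0]
    best = 1e30
    for k in range(npts):
        m = k % 3
        if m == 0:      # uniform in the volume
            while True:
                x = (np.random.random() * 2.0 - 1.0) * R
                y = (np.random.random() * 2.0 - 1.0) * R
                if x * x + y * y <= R * R:
                    break
            z = (np.random.random() * 2.0 - 1.0) * hL
        elif m == 1:    # lateral surface
            th = np.random.random() * 2.0 * np.pi
            x, y = R * np.cos(th), R * np.sin(th)
            z = (np.random.random() * 2.0 - 1.0) * hL
        else:           # caps
            while True:
                x = (np.random.random() * 2.0 - 1.0) * R
                y = (np.random.random() * 2.0 - 1.0) * R
                if x * x + y * y <= R * R:
                    break
            z = hL if np.random.random() < 0.5 else -hL
        px = pa[0] + z * aa[0] + x * u[0] + y * w[0]
        py = pa[1] + z * aa[1] + x * u[1] + y * w[1]
        pz = pa[2] + z * aa[2] + x * u[2] + y * w[2]
        d = signed_distance_point_cylinder(px, py, pz, pb, ab, hL, R)
        if d < best:
            best = d
    return best


def form_factor_brute(q: float, D: float, L: float, n: int = 20001) -> float:
    """Dense fixed-grid Simpson integration of the cylinder form factor."""
    R = 0.5 * D
    a = np.linspace(1e-9, np.pi / 2.0, n)
    x = q * R * np.sin(a)
    y = 0.5 * q * L * np.cos(a)
    fx = np.where(np.abs(x) > 1e-10, 2.0 * special.j1(x) / np.where(x == 0, 1, x), 1.0)
    fy = np.where(np.abs(y) > 1e-10, np.sin(y) / np.where(y == 0, 1, y), 1.0)
    return float(simpson((fx * fy) ** 2 * np.sin(a), x=a))


def cylinder_moments_closed_form(D: float, L: float) -> tuple[float, float]:
    """(second moment about center = Rg^2, axial second moment) of a uniform
    cylinder, from the textbook closed forms."""
    rg2 = L ** 2 / 12.0 + D ** 2 / 8.0
    return rg2, L ** 2 / 12.0
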