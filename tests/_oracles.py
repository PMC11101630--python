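"""Independent reference computations used to check the library.

Each oracle is deliberately written by a different route than the
implementation it checks (explicit loops, closed forms, eigendecompositions,
the quaternion superposition method) so agreement is meaningful.
"""

import numpy as np


def sphere_cap_sasa_two_atoms(R: float, d: float) -> float:
    """Exact SASA of one of two equal spheres of radius R at separation d.

    The buried part is a spherical cap of height h = R - d/2; accessible
    area = 4*pi*R^2 - 2*pi*R*h.
    """
    h = R - d / 2.0
    if h <= 0:
        return 4.0 * np.pi * R * R
    return 4.0 * np.pi * R * R - 2.0 * np.pi * R * h


def brute_force_contacts(coords_a, coords_b, cutoff) -> int:
    """O(n*m) double loop over all pairs."""
    n = 0
    for a in np.asarray(coords_a, dtype=float):
        for b in np.asarray(coords_b, dtype=float):
            if np.sqrt(np.sum((a - b) ** 2)) <= cutoff:
                n += 1
    return n


def plane_rmsd_by_eigendecomposition(coords) -> float:
    """Out-of-plane RMSD via a full eigendecomposition of the covariance."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    w, v = np.linalg.eigh(cov)
    normal = v[:, np.argmin(w)]
    return float(np.sqrt(np.mean((centered @ normal) ** 2)))


def lateral_offset_by_projection_matrix(normal, centroid_a, centroid_b) -> float:
    """Slip via the explicit projector P = I - n n^T onto the plane."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    p = np.eye(3) - np.outer(n, n)
    return float(np.linalg.norm(p @ (np.asarray(centroid_b) - np.asarray(centroid_a))))


def quaternion_superpose_rmsd(moving, reference) -> float:
    """Optimal superposition RMSD by the Kearsley quaternion method."""
    x = np.asarray(moving, dtype=float)
    y = np.asarray(reference, dtype=float)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    m = x - y
    p = x + y
    xm, ym, zm = m[:, 0], m[:, 1], m[:, 2]
    xp, yp, zp = p[:, 0], p[:, 1], p[:, 2]
    k = np.empty((4, 4))
    k[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    k[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    k[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    k[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    k[0, 1] = k[1, 0] = np.sum(yp * zm - ym * zp)
    k[0, 2] = k[2, 0] = np.sum(xm * zp - xp * zm)
    k[0, 3] = k[3, 0] = np.sum(xp * ym - xm * yp)
    k[1, 2] = k[2, 1] = np.sum(xm * ym - xp * yp)
    k[1, 3] = k[3, 1] = np.sum(xm * zm - xp * zp)
    k[2, 3] = k[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(k)[0]
    return float(np.sqrt(max(lam, 0.0) / len(x)))


def wilson_interval(count: int, n: int, z: float = 1.959963984540054):
    """Closed-form Wilson score interval for a binomial proportion."""
    p = count / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def two_proportion_z(c1: int, n1: int, c2: int, n2: int) -> float:
    """Pooled two-proportion z statistic (textbook form)."""
    p1, p2 = c1 / n1, c2 / n2
    pool = (c1 + c2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return float((p1 - p2) / se)


def random_rigid_transform(rng):
    """Uniform random proper rotation (QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def voxel_counts_by_scan(values, level) -> int:
    """Exhaustive triple-loop voxel count at an isovalue."""
    n = 0
    vx = np.asarray(values)
    for i in range(vx.shape[0]):
        for j in range(vx.shape[1]):
            for k in range(vx.shape[2]):
                if vx[i, j, k] >= level:
                    n += 1
    return n
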