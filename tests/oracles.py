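"""Independent reference implementations used only to check the package.

Each oracle deliberately uses a different algorithm from the code under
test: all-pairs distance matrices for the k-d-tree contact engine, Horn's
quaternion method for the SVD-based superposition, latitude–longitude
quadrature for the Fibonacci-lattice SASA, and direct summation for the
FFT-free convolution.
"""

from __future__ import annotations

import numpy as np


def brute_force_contacts(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> set:
    """O(N²) all-pairs contact set."""
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(d <= cutoff))}


def horn_quaternion_fit(mobile: np.ndarray, ref: np.ndarray) -> float:
    """RMSD after optimal proper-rotation fit, via Horn's quaternion method."""
    p = mobile - mobile.mean(axis=0)
    q = ref - ref.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e = float((p ** 2).sum() + (q ** 2).sum() - 2.0 * lam)
    return np.sqrt(max(e, 0.0) / len(p))


def latlong_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
                 n_theta: int = 90, n_phi: int = 180) -> np.ndarray:
    """Per-atom SASA by latitude–longitude quadrature on the inflated sphere.

    Area weights are sin(θ) dθ dφ; independent of the Fibonacci point set
    used by the implementation.
    """
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.column_stack(
        [ (np.sin(tt) * np.cos(pp)).ravel(),
          (np.sin(tt) * np.sin(pp)).ravel(),
          np.cos(tt).ravel() ]
    )
    w = (np.sin(tt).ravel()) * (np.pi / n_theta) * (2.0 * np.pi / n_phi)
    ext = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * dirs
        accessible = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= ext[j] ** 2
        out[i] = ext[i] ** 2 * float((w * accessible).sum())
    return out


def naive_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-sum 'same'-mode convolution with zero padding."""
    h = (len(kernel) - 1) // 2
    n = len(x)
    out = np.zeros(n)
    for p in range(n):
        for d in range(-h, h + 1):
            q = p - d
            if 0 <= q < n:
                out[p] += kernel[h + d] * x[q]
    return out


def dwell_events_reference(states: np.ndarray, dt: float) -> list[tuple[int, int]]:
    """Maximal bound stretches of a boolean series as (start_idx, end_idx)."""
    out = []
    i, n = 0, len(states)
    while i < n:
        if states[i]:
            j = i
            while j + 1 < n and states[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out
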