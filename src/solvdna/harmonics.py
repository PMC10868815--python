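"""Real regular solid harmonics and their rotation matrices.

Convention: for degree l the (2l+1) components are ordered m = -l..+l and
are the real solid harmonics S_lm(r) (homogeneous harmonic polynomials,
which carry the r^l radial factor) in the Racah-style normalisation

    integral over the unit sphere of S_lm * S_lm' dOmega
        = 4*pi / (2l+1) * delta_mm'.

Explicitly (m = -l..l):

    l=0:  1
    l=1:  y, z, x
    l=2:  sqrt(3) xy, sqrt(3) yz, (3z^2 - r^2)/2, sqrt(3) xz,
          sqrt(3)/2 (x^2 - y^2)

No Condon-Shortley phases.  The supported maximum degree is 2, matching
the shipped auxiliary basis.
"""

from __future__ import annotations

import numpy as np

LMAX = 2


def n_components(l: int) -> int:
    return 2 * l + 1


def solid_harmonics(l: int, vec: np.ndarray) -> np.ndarray:
    """Evaluate the real solid harmonics of degree ``l``.

    Parameters
    ----------
    l : int
        Degree, 0 <= l <= 2.
    vec : (..., 3) array
        Displacement vectors.

    Returns
    -------
    (..., 2l+1) array in m = -l..+l order.
    """
    vec = np.asarray(vec, dtype=float)
    x, y, z = vec[..., 0], vec[..., 1], vec[..., 2]
    if l == 0:
        return np.ones(vec.shape[:-1] + (1,))
    if l == 1:
        return np.stack([y, z, x], axis=-1)
    if l == 2:
        s3 = np.sqrt(3.0)
        r2 = x * x + y * y + z * z
        return np.stack(
            [s3 * x * y, s3 * y * z, 0.5 * (3 * z * z - r2), s3 * x * z, 0.5 * s3 * (x * x - y * y)],
            axis=-1,
        )
    raise NotImplementedError(f"Solid harmonics implemented for l <= {LMAX}, got l={l}.")


def rotation_matrix(l: int, R: np.ndarray) -> np.ndarray:
    """Real (2l+1)x(2l+1) rotation matrix D with S_l(R r) = D @ S_l(r).

    Computed numerically by sampling: S_lm is a basis of the degree-l
    harmonic polynomials, so D is obtained from a least-squares solve over
    a fixed set of sample directions.  Exact to machine precision because
    the relation is linear.
    """
    R = np.asarray(R, dtype=float)
    if l == 0:
        return np.ones((1, 1))
    rng = np.random.default_rng(20240215 + l)
    pts = rng.normal(size=(max(12, 4 * (2 * l + 1)), 3))
    A = solid_harmonics(l, pts)            # (npts, 2l+1)
    B = solid_harmonics(l, pts @ R.T)      # S(R r)
    D, *_ = np.linalg.lstsq(A, B, rcond=None)
    return D.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
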