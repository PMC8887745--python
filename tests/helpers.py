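"""Independent numerical oracles used by the test suite."""

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve


def laplace_streamfunction_velocities(model, extent, n=81):
    """Brute-force finite-difference solution of the depth-averaged flow.

    Solves Laplace's equation for the streamfunction psi on an n x n grid
    over [-extent, extent]^2 with Dirichlet conditions: the analytic far
    field on the outer box and psi = 0 on the obstacle (its surface is a
    streamline). Velocities follow from central differences,
    u = dpsi/dy, v = -dpsi/dx. Entirely independent of the package's
    complex-velocity evaluation.

    Returns (points, velocities, r) for the interior points where the
    central-difference stencil is available.
    """
    U = model.mean_speed
    a = model.obstacle.radius
    xs = np.linspace(-extent, extent, n)
    h = xs[1] - xs[0]
    X, Y = np.meshgrid(xs, xs)
    R = np.hypot(X, Y)

    def psi_exact(x, y):
        r2 = np.maximum(x**2 + y**2, 1e-12)  # center is masked as solid
        return U * x * (1.0 - a**2 / r2)

    solid = R <= a
    boundary = np.zeros_like(solid)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    fixed = solid | boundary
    psi = np.where(solid, 0.0, psi_exact(X, Y))

    idx = -np.ones((n, n), dtype=int)
    free = ~fixed
    idx[free] = np.arange(free.sum())
    A = lil_matrix((free.sum(), free.sum()))
    b = np.zeros(free.sum())
    for j in range(n):
        for i in range(n):
            k = idx[j, i]
            if k < 0:
                continue
            A[k, k] = -4.0
            for jj, ii in ((j - 1, i), (j + 1, i), (j, i - 1), (j, i + 1)):
                kk = idx[jj, ii]
                if kk >= 0:
                    A[k, kk] = 1.0
                else:
                    b[k] -= psi[jj, ii]
    sol = spsolve(A.tocsr(), b)
    psi_num = psi.copy()
    psi_num[free] = sol

    u = np.gradient(psi_num, h, axis=0)       # dpsi/dy (rows are y)
    v = -np.gradient(psi_num, h, axis=1)      # -dpsi/dx
    inner = np.ones_like(solid)
    inner[0, :] = inner[-1, :] = inner[:, 0] = inner[:, -1] = False
    ok = inner.astype(bool) & ~solid
    pts = np.column_stack([X[ok], Y[ok]])
    vel = np.column_stack([u[ok], v[ok]])
    return pts, vel, R[ok]
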