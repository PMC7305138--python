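"""Independent brute-force oracle for biharmonic in-painting.

Builds the full dense linear system for the missing pixels with explicit
Python loops and solves it with numpy.linalg.solve.  Shares no code with
csxrf.reconstruction: equations are written out term by term so the two
routes agree only if both implement the stencil correctly.

Stencil definition (the dialect under test): for a missing pixel whose full
13-point bilaplacian neighbourhood lies inside the grid,

    20 u(r,c) - 8 [u(r±1,c) + u(r,c±1)] + 2 [u(r±1,c±1)] + [u(r±2,c) + u(r,c±2)] = 0 ;

for any other missing pixel, the 5-point Laplace equation restricted to
in-grid orthogonal neighbours,

    k u(r,c) - sum_in-grid-orthogonal u = 0,   k = number of such neighbours.

Known pixels are substituted by their values (moved to the right-hand side).
"""

import numpy as np


def dense_biharmonic_inpaint(values, missing):
    values = np.asarray(values, float)
    missing = np.asarray(missing, bool)
    n_rows, n_cols = values.shape
    unknowns = [(r, c) for r in range(n_rows) for c in range(n_cols) if missing[r, c]]
    if not unknowns:
        return values.copy()
    index = {pix: i for i, pix in enumerate(unknowns)}
    n = len(unknowns)
    a = np.zeros((n, n))
    b = np.zeros(n)

    def add(i, r, c, coeff):
        if (r, c) in index:
            a[i, index[(r, c)]] += coeff
        else:
            b[i] -= coeff * values[r, c]

    for i, (r, c) in enumerate(unknowns):
        if 2 <= r <= n_rows - 3 and 2 <= c <= n_cols - 3:
            add(i, r, c, 20.0)
            add(i, r - 1, c, -8.0)
            add(i, r + 1, c, -8.0)
            add(i, r, c - 1, -8.0)
            add(i, r, c + 1, -8.0)
            add(i, r - 1, c - 1, 2.0)
            add(i, r - 1, c + 1, 2.0)
            add(i, r + 1, c - 1, 2.0)
            add(i, r + 1, c + 1, 2.0)
            add(i, r - 2, c, 1.0)
            add(i, r + 2, c, 1.0)
            add(i, r, c - 2, 1.0)
            add(i, r, c + 2, 1.0)
        else:
            k = 0
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    add(i, rr, cc, -1.0)
                    k += 1
            add(i, r, c, float(k))

    x = np.linalg.solve(a, b)
    out = values.copy()
    for i, (r, c) in enumerate(unknowns):
        out[r, c] = x[i]
    return out
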