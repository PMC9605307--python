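"""Independent from-scratch oracles used to cross-check the implementation.

Everything here is deliberately naive — plain-Python Gaussian elimination and
textbook sums of squares — so it shares no code path with the package or with
numpy.linalg's solvers.
"""

from __future__ import annotations

import math


def gauss_rank(matrix, tol: float = 1e-9) -> int:
    """Rank by Gaussian elimination with partial pivoting (pure Python)."""
    A = [list(map(float, row)) for row in matrix]
    n_rows = len(A)
    n_cols = len(A[0]) if n_rows else 0
    rank = 0
    row = 0
    for col in range(n_cols):
        pivot = max(range(row, n_rows), key=lambda r: abs(A[r][col]),
                    default=None)
        if pivot is None or abs(A[pivot][col]) < tol:
            continue
        A[row], A[pivot] = A[pivot], A[row]
        pv = A[row][col]
        for r in range(row + 1, n_rows):
            f = A[r][col] / pv
            for c in range(col, n_cols):
                A[r][c] -= f * A[row][c]
        row += 1
        rank += 1
        if row == n_rows:
            break
    return rank


def gauss_solve(A, b):
    """Solve a square linear system by Gauss-Jordan elimination (pure Python)."""
    n = len(A)
    M = [list(map(float, row)) + [float(b[i])] for i, row in enumerate(A)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(M[r][col]))
        if abs(M[pivot][col]) < 1e-12:
            raise ValueError("singular system")
        M[col], M[pivot] = M[pivot], M[col]
        pv = M[col][col]
        M[col] = [v / pv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0.0:
                f = M[r][col]
                M[r] = [vr - f * vc for vr, vc in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def normal_equations_ols(X_rows, y):
    """OLS of y on [1 | X] via explicitly formed normal equations."""
    rows = [[1.0] + list(map(float, r)) for r in X_rows]
    p = len(rows[0])
    AtA = [[sum(r[i] * r[j] for r in rows) for j in range(p)] for i in range(p)]
    Aty = [sum(r[i] * yi for r, yi in zip(rows, y)) for i in range(p)]
    return gauss_solve(AtA, Aty)


def ols_inference(X_rows, y):
    """Textbook OLS with per-coefficient SE and t (no p; caller uses scipy).

    Returns (beta, se, t) lists over [intercept, x1..xp].
    """
    rows = [[1.0] + list(map(float, r)) for r in X_rows]
    n, p = len(rows), len(rows[0])
    beta = normal_equations_ols(X_rows, y)
    resid = [yi - sum(b * v for b, v in zip(beta, r)) for r, yi in zip(rows, y)]
    s2 = sum(e * e for e in resid) / (n - p)
    AtA = [[sum(r[i] * r[j] for r in rows) for j in range(p)] for i in range(p)]
    # invert AtA column by column
    inv_diag = []
    for j in range(p):
        e = [1.0 if i == j else 0.0 for i in range(p)]
        col = gauss_solve(AtA, e)
        inv_diag.append(col[j])
    se = [math.sqrt(s2 * d) for d in inv_diag]
    t = [b / s for b, s in zip(beta, se)]
    return beta, se, t


def pearson_r(u, v) -> float:
    """From-scratch Pearson correlation."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = math.sqrt(sum((a - mu) ** 2 for a in u))
    sv = math.sqrt(sum((b - mv) ** 2 for b in v))
    return cov / (su * sv)


def oneway_anova_F(groups):
    """Textbook one-way ANOVA: (F, df_between, df_within)."""
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w
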