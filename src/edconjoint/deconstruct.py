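"""Top-box binarization and part-worth OLS models.

Ratings on the 1-9 scale are collapsed to a 0/100 top-3-box variable
(7-9 -> 100, 1-6 -> 0) so that OLS coefficients read directly as percentage
points of top-3-box probability.  Each respondent gets an individual model

    y_hat = b0 + b1 x1 + ... + bp xp

regressing the binarized ratings on the presence/absence dummies of the 36
messages; the permuted incomplete design guarantees a unique solution.  Group
models pool the stacked rows of a respondent group into a single regression
and report conventional OLS inference (SE, t, two-sided p) per message.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

TOP_BOX_THRESHOLD = 7
#: group coefficients at or above this are flagged by the conventional
#: rule of thumb used with this methodology (coefficient >= 6, given group
#: standard errors near 4); reported alongside genuine t-based p-values.
HEURISTIC_SIGNIFICANCE_CUTOFF = 6.0


class ModelError(ValueError):
    pass


def binarize(rating):
    """Map 1-9 ratings to the 0/100 top-3-box scale (7-9 -> 100, else 0).

    Accepts scalars or arrays; non-integer or out-of-range values raise.
    """
    arr = np.asarray(rating)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ModelError("ratings must be integers in 1..9")
        arr = arr.astype(int)
    if arr.size and (arr.min() < 1 or arr.max() > 9):
        raise ModelError("ratings must lie in 1..9")
    out = np.where(arr >= TOP_BOX_THRESHOLD, 100.0, 0.0)
    return float(out) if np.isscalar(rating) else out


@dataclass
class RespondentModel:
    """Individual part-worth model: constant + one coefficient per message."""

    respondent_id: str
    constant: float
    coefficients: dict[str, float]
    residual_se: float
    full_rank: bool = True

    def coefficient_vector(self, message_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = message_ids or list(self.coefficients)
        return np.array([self.coefficients[m] for m in ids])


@dataclass
class GroupModel:
    """Pooled OLS over a respondent group's stacked rows."""

    label: str
    constant: float
    constant_se: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    n_respondents: int
    n_obs: int

    def coefficient_vector(self, message_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = message_ids or list(self.coefficients)
        return np.array([self.coefficients[m] for m in ids])

    def to_frame(self) -> pd.DataFrame:
        """Report table: constant row first, then messages by descending
        coefficient, with SE / t / p and the coefficient>=6 heuristic flag."""
        rows = [{
            "term": "Additive constant",
            "coefficient": self.constant,
            "std_error": self.constant_se,
            "t": self.constant / self.constant_se if self.constant_se else np.nan,
            "p": np.nan,
            "heuristic_significant": self.constant >= HEURISTIC_SIGNIFICANCE_CUTOFF,
        }]
        order = sorted(self.coefficients,
                       key=lambda m: -self.coefficients[m])
        for m in order:
            rows.append({
                "term": m,
                "coefficient": self.coefficients[m],
                "std_error": self.std_errors[m],
                "t": self.t_values[m],
                "p": self.p_values[m],
                "heuristic_significant":
                    self.coefficients[m] >= HEURISTIC_SIGNIFICANCE_CUTOFF,
            })
        return pd.DataFrame(rows)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def fit_respondent_model(X, y, respondent_id: str = "") -> RespondentModel:
    """Exact normal-equations OLS of binarized ratings on [1 | presence].

    ``X`` is the (n_vignettes x n_messages) presence matrix (DataFrame columns
    become coefficient keys); ``y`` the binarized 0/100 responses.  A
    rank-deficient design raises — an upstream design bug must never yield a
    silent pseudo-solution.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.shape != (n,):
        raise ModelError(f"y has shape {y.shape}, expected ({n},)")
    A = np.hstack([np.ones((n, 1)), Xm])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ModelError(
            f"design matrix for {respondent_id or 'respondent'} is rank "
            "deficient; refusing to pseudo-solve"
        )
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    dof = n - (p + 1)
    residual_se = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return RespondentModel(
        respondent_id=respondent_id,
        constant=float(beta[0]),
        coefficients={m: float(b) for m, b in zip(names, beta[1:])},
        residual_se=residual_se,
        full_rank=True,
    )


def fit_group_model(pairs: Sequence[tuple], label: str = "group") -> GroupModel:
    """Single pooled OLS over a group's stacked (presence, binarized-y) rows.

    ``pairs`` holds one ``(X, y)`` tuple per respondent.  Inference (SE, t,
    two-sided p from the t distribution) uses the stacked-system residual
    degrees of freedom.
    """
    if not pairs:
        raise ModelError("empty group")
    mats, names0 = [], None
    ys = []
    for X, y in pairs:
        Xm, names = _as_matrix(X)
        if names0 is None:
            names0 = names
        elif names != names0:
            raise ModelError("inconsistent design columns across respondents")
        mats.append(Xm)
        ys.append(np.asarray(y, dtype=float))
    Xall = np.vstack(mats)
    yall = np.concatenate(ys)
    A = sm.add_constant(Xall, has_constant="add")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ModelError(f"pooled design for {label!r} is rank deficient")
    res = sm.OLS(yall, A).fit()
    assert names0 is not None
    return GroupModel(
        label=label,
        constant=float(res.params[0]),
        constant_se=float(res.bse[0]),
        coefficients={m: float(b) for m, b in zip(names0, res.params[1:])},
        std_errors={m: float(s) for m, s in zip(names0, res.bse[1:])},
        t_values={m: float(t) for m, t in zip(names0, res.tvalues[1:])},
        p_values={m: float(p) for m, p in zip(names0, res.pvalues[1:])},
        n_respondents=len(pairs),
        n_obs=len(yall),
    )


def fit_panel(book, table, label: str = "total panel"):
    """Convenience: individual models plus the pooled panel model.

    Returns ``(respondent_models, group_model, data)`` where ``data`` maps
    respondent id -> (presence DataFrame, binarized y), reusable for
    per-mindset re-estimation.
    """
    from .design import design_matrix

    models: dict[str, RespondentModel] = {}
    data: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    for rid in book.respondent_ids:
        X = design_matrix(book, rid)
        y = binarize(table.for_respondent(rid))
        models[rid] = fit_respondent_model(X, y, respondent_id=rid)
        data[rid] = (X, y)
    group = fit_group_model(list(data.values()), label=label)
    return models, group, data
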