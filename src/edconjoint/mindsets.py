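"""Mindset segmentation: correlation-distance k-means over part-worth vectors.

Respondents are clustered on the *shape* of their 36 part-worth coefficients
using the 1 - Pearson-r distance.  k-means under that metric is realized as
ordinary Euclidean k-means on row-standardized vectors (each respondent's
coefficients centered to zero mean and scaled to unit norm): for unit-norm
centered vectors, squared Euclidean distance is 2(1 - r), so the two
objectives are monotonically equivalent and the centroid update stays closed
form.  After clustering, each mindset's group model is re-estimated by pooled
OLS on all raw data from that mindset's respondents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .deconstruct import GroupModel, RespondentModel, fit_group_model
from .simulate import MindsetProfile

logger = logging.getLogger(__name__)

LOW_SEPARATION_SILHOUETTE = 0.25


class MindsetError(ValueError):
    pass


def correlation_distance(u, v) -> float:
    """1 - Pearson correlation between two coefficient vectors (range [0, 2])."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise MindsetError("vectors must be one-dimensional and equal length")
    du = u - u.mean()
    dv = v - v.mean()
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0.0 or nv == 0.0:
        raise MindsetError("zero-variance coefficient vector has no correlation")
    return float(1.0 - du @ dv / (nu * nv))


def _standardized_rows(models: Sequence[RespondentModel],
                       message_ids: Sequence[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    ids = list(message_ids) if message_ids else list(models[0].coefficients)
    B = np.array([m.coefficient_vector(ids) for m in models])
    B = B - B.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(B, axis=1)
    bad = [models[i].respondent_id for i in np.nonzero(norms == 0)[0]]
    if bad:
        raise MindsetError(
            f"zero-variance coefficient vector(s) for respondents {bad}"
        )
    return B / norms[:, None], ids


@dataclass
class MindsetSolution:
    """A k-cluster segmentation plus its re-estimated group models."""

    k: int
    assignment: dict[str, int]
    group_models: list[GroupModel]
    base_sizes: list[int]
    respondent_models: list[RespondentModel] = field(default_factory=list)
    silhouette_by_k: dict[int, float] | None = None
    anova: pd.DataFrame | None = None
    seed: int | None = None
    restarts: int | None = None

    def __post_init__(self) -> None:
        if self.assignment:
            sizes = np.bincount(list(self.assignment.values()), minlength=self.k)
            if list(sizes) != list(self.base_sizes):
                raise MindsetError("base sizes disagree with assignment")
            if (sizes == 0).any():
                raise MindsetError("empty mindset")

    def members(self, mindset: int) -> list[str]:
        return [r for r, g in self.assignment.items() if g == mindset]


def cluster_respondents(models: Sequence[RespondentModel], k: int, seed: int = 0,
                        restarts: int = 50,
                        data: Mapping[str, tuple] | None = None,
                        message_ids: Sequence[str] | None = None
                        ) -> MindsetSolution:
    """k-means under correlation distance, best of ``restarts`` inits.

    ``data`` maps respondent id -> (presence matrix, binarized y); when given,
    each mindset's GroupModel is the pooled OLS over its members' raw rows.
    Without raw data the group "model" summarizes the members' individual
    coefficients (mean, SE across respondents) — useful for quick looks, while
    the pooled fit is the reporting standard.
    """
    if not 2 <= k <= len(models):
        raise MindsetError(f"need n >= k >= 2, got n={len(models)}, k={k}")
    Z, ids = _standardized_rows(models, message_ids)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=_sk_seed(seed))
    labels = km.fit_predict(Z)
    # relabel clusters by size (largest first) so output order is stable
    order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    assignment = {m.respondent_id: int(l) for m, l in zip(models, labels)}
    base_sizes = [int(c) for c in np.bincount(labels, minlength=k)]
    group_models = []
    for g in range(k):
        members = [m for m, l in zip(models, labels) if l == g]
        if data is not None:
            pairs = [data[m.respondent_id] for m in members]
            group_models.append(fit_group_model(pairs, label=f"mindset {g + 1}"))
        else:
            group_models.append(_summary_group_model(members, ids, f"mindset {g + 1}"))
    return MindsetSolution(k=k, assignment=assignment, group_models=group_models,
                           base_sizes=base_sizes,
                           respondent_models=list(models), seed=seed,
                           restarts=restarts)


def _sk_seed(seed: int) -> int:
    return int(seed) % (2**31 - 1)


def _summary_group_model(members: Sequence[RespondentModel], ids: Sequence[str],
                         label: str) -> GroupModel:
    B = np.array([m.coefficient_vector(ids) for m in members])
    consts = np.array([m.constant for m in members])
    n = len(members)
    se = B.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(B.shape[1], np.nan)
    mean = B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    p = 2 * stats.t.sf(np.abs(t), df=max(n - 1, 1))
    return GroupModel(
        label=label,
        constant=float(consts.mean()),
        constant_se=float(consts.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        coefficients=dict(zip(ids, mean)),
        std_errors=dict(zip(ids, se)),
        t_values=dict(zip(ids, t)),
        p_values=dict(zip(ids, p)),
        n_respondents=n,
        n_obs=n,
    )


def select_k(models: Sequence[RespondentModel],
             k_range: Sequence[int] = range(2, 7), seed: int = 0,
             restarts: int = 50) -> tuple[int, dict[int, float]]:
    """Mean silhouette (correlation distance) per k; returns (argmax, profile).

    Emits a low-separation warning when even the best k stays below
    ``LOW_SEPARATION_SILHOUETTE``.
    """
    ks = list(k_range)
    if len(models) <= max(ks):
        raise MindsetError("need more respondents than max(k_range)")
    Z, _ = _standardized_rows(models)
    # pairwise 1 - r; for unit-norm centered rows r = dot product
    D = np.clip(1.0 - Z @ Z.T, 0.0, None)
    np.fill_diagonal(D, 0.0)
    profile: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=_sk_seed(seed))
        labels = km.fit_predict(Z)
        profile[k] = float(silhouette_score(D, labels, metric="precomputed"))
    chosen = max(profile, key=lambda k: profile[k])
    if profile[chosen] < LOW_SEPARATION_SILHOUETTE:
        warnings.warn(
            f"low cluster separation: best mean silhouette {profile[chosen]:.3f} "
            f"(k={chosen}) is below {LOW_SEPARATION_SILHOUETTE}",
            stacklevel=2,
        )
    return chosen, profile


def compare_mindsets(solution: MindsetSolution) -> pd.DataFrame:
    """Per-message one-way ANOVA + Tukey HSD over per-respondent coefficients.

    Returns one row per message with the F statistic, p value, a significance
    flag at p < 0.05, Tukey adjusted p per mindset pair, and a ``degenerate``
    flag where group variances vanish (such messages are flagged, not fatal).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if solution.k < 2:
        raise MindsetError("need at least two mindsets to compare")
    if min(solution.base_sizes) < 2:
        raise MindsetError("every mindset needs n >= 2 for ANOVA")
    models = solution.respondent_models
    ids = list(models[0].coefficients)
    labels = np.array([solution.assignment[m.respondent_id] for m in models])
    rows = []
    pair_names = [
        f"tukey_p_{a + 1}v{b + 1}"
        for a in range(solution.k) for b in range(a + 1, solution.k)
    ]
    for mid in ids:
        vals = np.array([m.coefficients[mid] for m in models])
        groups = [vals[labels == g] for g in range(solution.k)]
        degenerate = all(np.ptp(g) == 0 for g in groups)
        row: dict = {"message": mid, "degenerate": degenerate}
        if degenerate:
            if all(np.isclose(g.mean(), groups[0].mean()) for g in groups):
                row.update(F=0.0, p=1.0, significant=False)
            else:  # zero within-group variance but distinct means
                row.update(F=np.inf, p=0.0, significant=True)
            row.update({name: np.nan for name in pair_names})
        else:
            F, p = stats.f_oneway(*groups)
            row.update(F=float(F), p=float(p), significant=bool(p < 0.05))
            tk = pairwise_tukeyhsd(vals, labels)
            for name, padj in zip(pair_names, tk.pvalues):
                row[name] = float(padj)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out[["message", "F", "p", "significant", *pair_names, "degenerate"]]


def split_half_reliability(models: Sequence[RespondentModel], seed: int = 0,
                           data: Mapping[str, tuple] | None = None
                           ) -> tuple[float, float]:
    """Correlate each random half-panel's group coefficients with the total's.

    Group coefficients come from pooled OLS when raw ``data`` are supplied,
    otherwise from the mean of the members' individual coefficient vectors.
    Returns (r_half1_vs_total, r_half2_vs_total).
    """
    if len(models) < 4:
        raise MindsetError("need at least 4 respondents for a half-split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(models))
    halves = [sorted(idx[: len(idx) // 2]), sorted(idx[len(idx) // 2:])]
    ids = list(models[0].coefficients)

    def group_coefs(sub: Sequence[int] | None) -> np.ndarray:
        chosen = list(models) if sub is None else [models[i] for i in sub]
        if data is not None:
            gm = fit_group_model([data[m.respondent_id] for m in chosen])
            return gm.coefficient_vector(ids)
        return np.array([m.coefficient_vector(ids) for m in chosen]).mean(axis=0)

    total = group_coefs(None)
    r = tuple(
        float(stats.pearsonr(group_coefs(h), total).statistic) for h in halves
    )
    return r  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# recovery utilities


def match_to_profiles(solution: MindsetSolution,
                      profiles: Sequence[MindsetProfile],
                      message_ids: Sequence[str]) -> dict[int, int]:
    """Hungarian matching of clusters to generative profiles.

    Maximizes total Pearson correlation between each cluster's group
    coefficient vector and the profile's utility vector; returns
    {profile index -> cluster index}.  Ties (equal-correlation optima) resolve
    toward assigning larger clusters first via the assignment algorithm's
    deterministic output.
    """
    k = solution.k
    C = np.zeros((k, len(profiles)))
    for i, gm in enumerate(solution.group_models):
        u = gm.coefficient_vector(message_ids)
        for j, prof in enumerate(profiles):
            C[i, j] = 1.0 - correlation_distance(u, prof.utility_vector(message_ids))
    rows, cols = linear_sum_assignment(-C)
    return {int(j): int(i) for i, j in zip(rows, cols)}


def solution_from_profiles(profiles: Sequence[MindsetProfile],
                           message_ids: Sequence[str],
                           base_sizes: Sequence[int] | None = None
                           ) -> MindsetSolution:
    """A MindsetSolution carrying published group models directly.

    Used to drive tools that consume group models (e.g. the typing-tool
    builder) from known inputs rather than from a re-estimated segmentation.
    """
    sizes = list(base_sizes) if base_sizes is not None else [1] * len(profiles)
    gms = []
    for prof, n in zip(profiles, sizes):
        coefs = {m: prof.utility(m) for m in message_ids}
        nand = {m: np.nan for m in message_ids}
        gms.append(GroupModel(
            label=prof.label, constant=prof.constant, constant_se=np.nan,
            coefficients=coefs, std_errors=nand, t_values=nand, p_values=nand,
            n_respondents=n, n_obs=n,
        ))
    return MindsetSolution(k=len(profiles), assignment={}, group_models=gms,
                           base_sizes=sizes)


def mindset_report(solution: MindsetSolution,
                   anova: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide report: one row per message (plus base-size and constant rows),
    one column per mindset, with per-message significance flags when an
    ANOVA table is supplied."""
    ids = list(solution.group_models[0].coefficients)
    cols = [gm.label for gm in solution.group_models]
    head = pd.DataFrame(
        [["Base size", *solution.base_sizes],
         ["Additive constant", *[gm.constant for gm in solution.group_models]]],
        columns=["term", *cols],
    )
    body = pd.DataFrame(
        {"term": ids,
         **{gm.label: [gm.coefficients[m] for m in ids]
            for gm in solution.group_models}}
    )
    if anova is not None:
        flags = anova.set_index("message")["significant"]
        body["significant_between_mindsets"] = [bool(flags.get(m, False)) for m in ids]
    return pd.concat([head, body], ignore_index=True)
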