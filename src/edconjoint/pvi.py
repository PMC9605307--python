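"""Personal Viewpoint Identifier: a six-binary-question mindset typing tool.

Six messages are turned into agree/disagree questions.  A new individual's
six answers form one of 2^6 = 64 patterns; a lookup table maps every pattern
to the mindset whose simulated members produce it most often.  The six
questions are chosen by Monte-Carlo search: candidate subsets are sampled at
random (plus a greedy subset ranked by between-mindset spread, always
included), each is scored by simulating noisy virtual respondents per mindset
(perturbed utility = group coefficient + Gaussian answer noise; "agree" iff
the perturbed utility is positive), and the subset with the highest simulated
classification accuracy wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mindsets import MindsetSolution

logger = logging.getLogger(__name__)

N_QUESTIONS = 6


class PVIError(ValueError):
    pass


@dataclass
class PVISpec:
    """Six question messages + total pattern->mindset lookup (64 entries)."""

    question_ids: tuple[str, ...]
    pattern_table: dict[int, int]
    estimated_accuracy: float
    seed: int
    answer_noise_sd: float

    def __post_init__(self) -> None:
        if len(self.question_ids) != N_QUESTIONS:
            raise PVIError(f"expected {N_QUESTIONS} questions")
        if sorted(self.pattern_table) != list(range(2 ** N_QUESTIONS)):
            raise PVIError("pattern table must map all 64 answer patterns")
        if not set(self.pattern_table.values()):
            raise PVIError("pattern table maps to no mindset")

    def save(self, path: str | Path) -> None:
        payload = {
            "question_ids": list(self.question_ids),
            "pattern_table": {str(k): v for k, v in self.pattern_table.items()},
            "estimated_accuracy": self.estimated_accuracy,
            "seed": self.seed,
            "answer_noise_sd": self.answer_noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PVISpec":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            question_ids=tuple(payload["question_ids"]),
            pattern_table={int(k): int(v) for k, v in payload["pattern_table"].items()},
            estimated_accuracy=float(payload["estimated_accuracy"]),
            seed=int(payload["seed"]),
            answer_noise_sd=float(payload["answer_noise_sd"]),
        )


def _pattern_counts(coefs: np.ndarray, base: np.ndarray, noise_sd: float,
                    n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """counts[pattern, mindset] over n_sim virtual respondents per mindset."""
    k, q = coefs.shape
    counts = np.zeros((2 ** q, k))
    weights = 1 << np.arange(q)
    for g in range(k):
        u = coefs[g][None, :] + rng.normal(0.0, noise_sd, size=(n_sim, q))
        pats = ((u > 0.0).astype(np.int64) @ weights)
        counts[:, g] = np.bincount(pats, minlength=2 ** q)
    return counts


def _score(counts: np.ndarray, base_sizes: np.ndarray) -> tuple[float, dict[int, int]]:
    """Assign each pattern to its modal mindset (ties -> larger base size)
    and return (classification accuracy, pattern table)."""
    k = counts.shape[1]
    # tie-break toward larger base: stable argmax over (count, base size)
    order = np.argsort(-base_sizes, kind="stable")
    reordered = counts[:, order]
    best = order[np.argmax(reordered, axis=1)]
    table = {int(p): int(best[p]) for p in range(counts.shape[0])}
    total = counts.sum()
    correct = counts[np.arange(counts.shape[0]), best].sum()
    return float(correct / total), table


def build_pvi(solution: MindsetSolution, n_sim: int = 5000,
              answer_noise_sd: float = 10.0, n_candidate_subsets: int = 2000,
              seed: int = 0) -> PVISpec:
    """Choose the six most discriminating messages and build the lookup table.

    Monte-Carlo subset search over the messages of ``solution``'s group
    models; the returned spec's ``estimated_accuracy`` is the winning subset's
    simulated classification accuracy (fraction of virtual respondents whose
    answer pattern maps back to their own mindset).
    """
    if solution.k < 2:
        raise PVIError("need at least two mindsets with group models")
    ids = list(solution.group_models[0].coefficients)
    B = np.array([gm.coefficient_vector(ids) for gm in solution.group_models])
    if np.allclose(B, 0.0):
        raise PVIError("no discriminating signal: all group coefficients zero")
    base = np.array(solution.base_sizes, dtype=float)
    rng = np.random.default_rng(seed)

    # greedy seed subset: top messages by between-mindset spread
    spread = B.max(axis=0) - B.min(axis=0)
    greedy = tuple(sorted(np.argsort(-spread, kind="stable")[:N_QUESTIONS]))
    if len(ids) < N_QUESTIONS:
        raise PVIError(f"need at least {N_QUESTIONS} messages")
    from math import comb
    target = min(n_candidate_subsets + 1, comb(len(ids), N_QUESTIONS))
    candidates = {greedy}
    while len(candidates) < target:
        candidates.add(tuple(sorted(rng.choice(len(ids), N_QUESTIONS,
                                               replace=False).tolist())))

    best: tuple[float, tuple[int, ...], dict[int, int]] | None = None
    for subset in sorted(candidates):
        counts = _pattern_counts(B[:, list(subset)], base, answer_noise_sd,
                                 n_sim, rng)
        acc, table = _score(counts, base)
        if best is None or acc > best[0]:
            best = (acc, subset, table)
    acc, subset, table = best
    logger.info("PVI subset %s with simulated accuracy %.3f",
                [ids[i] for i in subset], acc)
    return PVISpec(
        question_ids=tuple(ids[i] for i in subset),
        pattern_table=table,
        estimated_accuracy=acc,
        seed=seed,
        answer_noise_sd=answer_noise_sd,
    )


def assign_mindset(spec: PVISpec, answers: Sequence[int | bool]) -> int:
    """Deterministic lookup: six agree(1)/disagree(0) answers -> mindset index."""
    if len(answers) != N_QUESTIONS:
        raise PVIError(f"expected {N_QUESTIONS} answers, got {len(answers)}")
    bits = []
    for a in answers:
        if a not in (0, 1, True, False):
            raise PVIError(f"answers must be binary, got {a!r}")
        bits.append(int(a))
    pattern = sum(b << i for i, b in enumerate(bits))
    return spec.pattern_table[pattern]


def held_out_accuracy(spec: PVISpec, solution: MindsetSolution, n_sim: int,
                      noise_sd: float, seed: int) -> float:
    """Fresh-simulation assignment accuracy of an already-built PVI."""
    ids = list(solution.group_models[0].coefficients)
    pos = [ids.index(q) for q in spec.question_ids]
    B = np.array([gm.coefficient_vector(ids) for gm in solution.group_models])
    rng = np.random.default_rng(seed)
    counts = _pattern_counts(B[:, pos], np.array(solution.base_sizes, float),
                             noise_sd, n_sim, rng)
    correct = sum(
        counts[p, g] for p, g in spec.pattern_table.items()
    )
    return float(correct / counts.sum())
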