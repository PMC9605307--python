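"""Synthetic respondents: latent mindset profiles -> 1-9 vignette ratings.

The generator works on the same scale the analysis estimates on.  A mindset
profile is an additive constant (the group's predisposition to rate a vignette
in the top three boxes, in percentage points) plus per-message part-worth
utilities (the percentage-point change in top-3-box probability when the
message is present).  A simulated respondent draws a personal constant around
the group constant, and rates each vignette by a linear-probability top-3-box
mechanism: with probability ``clamp((constant + sum of present utilities)/100)``
the rating is uniform over {7,8,9}, otherwise uniform over {1..6}.  The raw
1-9 values only exist so the binarization step has realistic input; the
expectation of the binarized response equals the clamped linear predictor, so
downstream OLS is unbiased for the generating parameters wherever no clamping
occurs.

The default profiles are the three published emergency-department mindsets
(constants 44 / 56 / 29 with nine listed message utilities each), and the
default group sizes are their base sizes 38 / 38 / 36.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignBook, design_matrix

DEFAULT_N_PER_MINDSET = (38, 38, 36)
DEFAULT_HETEROGENEITY_SD = 5.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class MindsetProfile:
    """A latent respondent group: additive constant + message utilities (pp)."""

    label: str
    constant: float
    utilities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.constant <= 100.0:
            raise SimulationError(
                f"profile constant {self.constant} outside [0, 100]"
            )
        if not all(np.isfinite(list(self.utilities.values()) or [0.0])):
            raise SimulationError("profile utilities must be finite")

    def utility(self, message_id: str) -> float:
        """Part-worth for a message; unlisted messages carry zero."""
        return float(self.utilities.get(message_id, 0.0))

    def utility_vector(self, message_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.utility(m) for m in message_ids])


@dataclass(frozen=True)
class SimulationConfig:
    n_per_mindset: tuple[int, ...] = DEFAULT_N_PER_MINDSET
    respondent_heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_mindset):
            raise SimulationError("n_per_mindset entries must be >= 1")
        if self.respondent_heterogeneity_sd < 0:
            raise SimulationError("heterogeneity sd must be >= 0")


@dataclass
class RatingsTable:
    """Long-format ratings; ``truth`` holds the generating mindset per
    respondent when the data are simulated."""

    ratings: pd.DataFrame  # columns: respondent_id, vignette_index, rating
    truth: dict[str, int] | None = None

    def for_respondent(self, respondent_id: str) -> np.ndarray:
        sub = self.ratings[self.ratings.respondent_id == respondent_id]
        return (sub.sort_values("vignette_index")["rating"]
                .to_numpy(dtype=int))

    def save(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        self.ratings.to_csv(path, index=False)
        if truth_path is not None and self.truth is not None:
            pd.DataFrame(
                {"respondent_id": list(self.truth),
                 "mindset": list(self.truth.values())}
            ).to_csv(truth_path, index=False)

    @classmethod
    def load(cls, path: str | Path,
             truth_path: str | Path | None = None) -> "RatingsTable":
        df = pd.read_csv(path)
        truth = None
        if truth_path is not None:
            t = pd.read_csv(truth_path)
            truth = dict(zip(t.respondent_id, t.mindset.astype(int)))
        tab = cls(ratings=df, truth=truth)
        tab.validate()
        return tab

    def validate(self) -> None:
        r = self.ratings["rating"]
        if not ((r >= 1) & (r <= 9)).all():
            raise SimulationError("ratings must lie in 1..9")
        if self.ratings.duplicated(["respondent_id", "vignette_index"]).any():
            raise SimulationError("duplicate (respondent, vignette) rows")


# ---------------------------------------------------------------------------
# published reference profiles

# Canonical message ids for the nine utilities listed per published mindset.
# The published table paraphrases the instrument texts; one row spans the
# "carefully listen"/"show interest" wording, keyed here as C1.
_REFERENCE_UTILITIES = {
    "C1": (8, 0, 5),    # carefully listen ... show interest in me as a person
    "D2": (6, -7, -1),  # allow family and friends to sit with me
    "C5": (0, 0, 8),    # attend to pain control
    "C3": (-1, -2, 7),  # discreet ... respect my privacy
    "B3": (2, 6, -3),   # explain things to me
    "E3": (-7, 9, 0),   # know the role of the clinician from the start
    "F5": (1, 6, -4),   # compassionate
    "B1": (2, 6, -4),   # keep me informed
    "A2": (4, 6, -6),   # concerned about my comfort
}
_REFERENCE_CONSTANTS = (44.0, 56.0, 29.0)


def reference_mindset_profiles() -> tuple[MindsetProfile, MindsetProfile, MindsetProfile]:
    """The three published ED-communication mindsets.

    MS1 ("pay attention to me"), MS2 ("professional and informative"),
    MS3 ("control my pain, respect my privacy"), with additive constants
    44 / 56 / 29 and the nine listed part-worth utilities each; the other 27
    messages carry zero by convention.
    """
    return tuple(
        MindsetProfile(
            label=f"MS{g + 1}",
            constant=_REFERENCE_CONSTANTS[g],
            utilities={m: float(v[g]) for m, v in _REFERENCE_UTILITIES.items()},
        )
        for g in range(3)
    )  # type: ignore[return-value]


# ---------------------------------------------------------------------------


def simulate_responses(book: DesignBook, profiles: Sequence[MindsetProfile],
                       config: SimulationConfig) -> RatingsTable:
    """Simulate 1-9 ratings for every respondent in ``book``.

    Respondents are partitioned over profiles in book order according to
    ``config.n_per_mindset`` (which must sum to the number of respondents).
    Deterministic given ``config.seed``.
    """
    if not profiles:
        raise SimulationError("profiles empty")
    if len(config.n_per_mindset) != len(profiles):
        raise SimulationError(
            f"{len(profiles)} profiles but {len(config.n_per_mindset)} group sizes"
        )
    ids = book.respondent_ids
    if sum(config.n_per_mindset) != len(ids):
        raise SimulationError(
            f"group sizes sum to {sum(config.n_per_mindset)} but the design "
            f"has {len(ids)} respondents"
        )
    rng = np.random.default_rng(config.seed)
    message_ids = book.instrument.message_ids
    rows = []
    truth: dict[str, int] = {}
    pos = 0
    for g, (profile, n_g) in enumerate(zip(profiles, config.n_per_mindset)):
        beta = profile.utility_vector(message_ids)
        for rid in ids[pos:pos + n_g]:
            truth[rid] = g
            X = design_matrix(book, rid).to_numpy()
            c_r = profile.constant + rng.normal(
                0.0, config.respondent_heterogeneity_sd)
            p = np.clip((c_r + X @ beta) / 100.0, 0.0, 1.0)
            top = rng.random(len(p)) < p
            rating = np.where(top,
                              rng.integers(7, 10, size=len(p)),
                              rng.integers(1, 7, size=len(p)))
            for i, r in enumerate(rating):
                rows.append((rid, i, int(r)))
        pos += n_g
    table = RatingsTable(
        ratings=pd.DataFrame(rows,
                             columns=["respondent_id", "vignette_index", "rating"]),
        truth=truth,
    )
    table.validate()
    return table
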