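"""Per-respondent permuted vignette designs.

Each respondent rates ``n_vignettes`` (default 48) vignettes, where a vignette
is a set of 2-4 messages drawn from distinct categories.  Vignettes are
incomplete on purpose: with complete one-per-category profiles the per-category
dummy blocks are collinear with the intercept and the individual-level
presence/absence regression (intercept + 36 message dummies) is not estimable.
With varying vignette sizes the 48 x 37 design matrix has full column rank and
every respondent's part-worth model has a unique OLS solution.

The generator builds one balanced *template* of vignette "slots" — category
patterns plus within-category slot indices, each (category, index) slot used
equally often — and gives every respondent an independent random permutation
of message indices within each category plus a random vignette order (the
"permuted design").  Permuting columns within categories and reordering rows
leaves the design matrix rank and conditioning unchanged, so the template is
validated once.  Among the feasible template draws inside the retry budget the
best-conditioned one (smallest mean coefficient-standard-error factor) is
kept, since the design's whole purpose is statistical independence of the
predictors.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .instrument import Instrument

TEMPLATE_RETRIES = 100
MIN_APPEARANCES = 4


class DesignError(ValueError):
    """Raised when a design cannot be generated or violates its invariants."""


@dataclass(frozen=True)
class Vignette:
    """A set of message ids shown together, at most one per category."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        letters = [m[0] for m in self.members]
        if len(set(letters)) != len(letters):
            raise DesignError(
                f"vignette {sorted(self.members)} has two messages from one category"
            )

    def __iter__(self):
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PermutationRecord:
    """Per-respondent randomization: within-category index maps + row order."""

    category_perms: dict[str, tuple[int, ...]]
    vignette_order: tuple[int, ...]

    def key(self) -> tuple:
        return (
            tuple(sorted((c, p) for c, p in self.category_perms.items())),
            self.vignette_order,
        )


@dataclass
class DesignBook:
    """All respondents' vignette lists plus the randomization that made them."""

    instrument: Instrument
    seed: int
    size_range: tuple[int, int]
    template: list[list[tuple[int, int]]]  # slots: (category index, slot index)
    vignettes: dict[str, list[Vignette]]
    permutations: dict[str, PermutationRecord] = field(default_factory=dict)

    @property
    def respondent_ids(self) -> list[str]:
        return list(self.vignettes)

    @property
    def n_vignettes(self) -> int:
        return len(next(iter(self.vignettes.values())))

    def __len__(self) -> int:
        return len(self.vignettes)


@dataclass
class RespondentCheck:
    rank: int
    full_rank: bool
    appearance_min: int
    appearance_max: int
    size_ok: bool
    n_vignettes_ok: bool

    @property
    def ok(self) -> bool:
        return (self.full_rank and self.size_ok and self.n_vignettes_ok
                and self.appearance_min >= MIN_APPEARANCES)


@dataclass
class DesignReport:
    """Quality gate over a DesignBook: rank, balance, uniqueness, collinearity."""

    per_respondent: dict[str, RespondentCheck]
    duplicate_respondents: list[tuple[str, str]]
    max_abs_column_correlation: float

    @property
    def all_ok(self) -> bool:
        return (not self.duplicate_respondents
                and all(c.ok for c in self.per_respondent.values()))


# ---------------------------------------------------------------------------
# template construction


def _choose_sizes(n_vignettes: int, size_range: tuple[int, int],
                  n_messages: int) -> list[int]:
    """Vignette sizes summing to a multiple of n_messages, with >=2 distinct
    sizes so the intercept is not collinear with the sum of the dummies."""
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise DesignError(f"bad size range {size_range}")
    reps = max(MIN_APPEARANCES,
               round(n_vignettes * (lo + hi) / 2 / n_messages))
    while reps * n_messages > n_vignettes * hi:
        reps -= 1
    if reps * n_messages < n_vignettes * lo or reps < MIN_APPEARANCES:
        raise DesignError(
            "infeasible parameters: cannot satisfy the minimum-appearance "
            f"constraint with {n_vignettes} vignettes of size {lo}-{hi}"
        )
    total = reps * n_messages
    # near-equal counts over the whole size range, then repair the sum by
    # moving single vignettes one size up or down
    span = list(range(lo, hi + 1))
    counts = {s: n_vignettes // len(span) for s in span}
    for s in span[: n_vignettes % len(span)]:
        counts[s] += 1
    deficit = total - sum(s * c for s, c in counts.items())
    while deficit > 0:
        s = min(s for s in span[:-1] if counts[s] > 0)
        counts[s] -= 1
        counts[s + 1] += 1
        deficit -= 1
    while deficit < 0:
        s = max(s for s in span[1:] if counts[s] > 0)
        counts[s] -= 1
        counts[s - 1] += 1
        deficit += 1
    if sum(1 for c in counts.values() if c > 0) < 2:
        raise DesignError(
            "infeasible parameters: uniform vignette size makes the "
            "intercept collinear with the message dummies"
        )
    sizes = [s for s in span for _ in range(counts[s])]
    return sorted(sizes, reverse=True)


def _draw_template(rng: np.random.Generator, sizes: Sequence[int],
                   n_cat: int, n_msg: int) -> list[list[tuple[int, int]]] | None:
    per_cat = sum(sizes) // n_cat
    counts = np.full(n_cat, per_cat)
    cat_lists: list[list[int]] = []
    for s in sizes:  # largest first: greedy largest-remaining stays feasible
        order = np.argsort(-(counts + rng.random(n_cat)))[:s]
        if counts[order[-1]] <= 0:
            return None
        for c in order:
            counts[c] -= 1
        cat_lists.append([int(c) for c in order])
    if counts.sum() != 0:
        return None
    reps = per_cat // n_msg
    pools = {
        c: list(rng.permutation(np.repeat(np.arange(n_msg), reps)))
        for c in range(n_cat)
    }
    return [[(c, int(pools[c].pop())) for c in cats] for cats in cat_lists]


def _template_matrix(template: Sequence[Sequence[tuple[int, int]]],
                     n_cat: int, n_msg: int) -> np.ndarray:
    X = np.zeros((len(template), n_cat * n_msg))
    for i, slots in enumerate(template):
        for c, j in slots:
            X[i, c * n_msg + j] = 1.0
    return X


def _se_factor(X: np.ndarray) -> float:
    """Mean per-coefficient standard-error multiplier sqrt(diag((A'A)^-1))."""
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    G = np.linalg.inv(A.T @ A)
    return float(np.sqrt(np.diag(G)[1:]).mean())


def generate_design(instrument: Instrument, n_respondents: int, seed: int,
                    n_vignettes: int = 48,
                    size_range: tuple[int, int] = (2, 4)) -> DesignBook:
    """Generate a permuted vignette design for ``n_respondents`` respondents.

    Deterministic in (instrument, n_respondents, seed).  The returned book
    satisfies, per respondent: exactly ``n_vignettes`` vignettes, every
    message appearing at least 4 times with appearance spread <= 2, and a
    full-rank (intercept + messages) design matrix.  Respondents' ordered
    vignette lists are pairwise distinct (verified).
    """
    if n_respondents < 1:
        raise DesignError("n_respondents must be >= 1")
    n_cat = instrument.n_categories
    n_msg = instrument.messages_per_category
    if size_range[1] > n_cat:
        raise DesignError("vignette size cannot exceed the number of categories")
    sizes = _choose_sizes(n_vignettes, size_range, n_cat * n_msg)
    rng = np.random.default_rng(seed)

    best: tuple[float, list[list[tuple[int, int]]]] | None = None
    for _ in range(TEMPLATE_RETRIES):
        template = _draw_template(rng, sizes, n_cat, n_msg)
        if template is None:
            continue
        X = _template_matrix(template, n_cat, n_msg)
        A = np.hstack([np.ones((n_vignettes, 1)), X])
        if np.linalg.matrix_rank(A) != n_cat * n_msg + 1:
            continue
        f = _se_factor(X)
        if best is None or f < best[0]:
            best = (f, template)
    if best is None:
        raise DesignError(
            "infeasible parameters: no full-rank template found within "
            f"{TEMPLATE_RETRIES} draws (rank constraint)"
        )
    template = best[1]

    ids = [f"r{i + 1:03d}" for i in range(n_respondents)]
    book = DesignBook(instrument=instrument, seed=seed, size_range=size_range,
                      template=template, vignettes={})
    seen: set[tuple] = set()
    letters = [chr(ord("A") + c) for c in range(n_cat)]
    for rid in ids:
        for _ in range(TEMPLATE_RETRIES):
            perms = {
                letters[c]: tuple(int(x) for x in rng.permutation(n_msg))
                for c in range(n_cat)
            }
            order = tuple(int(x) for x in rng.permutation(n_vignettes))
            rec = PermutationRecord(category_perms=perms, vignette_order=order)
            if rec.key() not in seen:
                seen.add(rec.key())
                break
        else:
            raise DesignError(
                "uniqueness constraint: could not draw a fresh permutation "
                f"record for {rid}"
            )
        vlist: list[Vignette | None] = [None] * n_vignettes
        for i, slots in enumerate(template):
            members = frozenset(
                f"{letters[c]}{perms[letters[c]][j] + 1}" for c, j in slots
            )
            vlist[order[i]] = Vignette(members=members)
        book.vignettes[rid] = vlist  # type: ignore[assignment]
        book.permutations[rid] = rec

    report = validate_design(book)
    if not report.all_ok:
        raise DesignError(f"generated design failed validation: {report}")
    return book


# ---------------------------------------------------------------------------
# matrices and validation


def design_matrix(book: DesignBook, respondent_id: str):
    """The 0/1 presence matrix (vignettes x messages) for one respondent.

    Returned as a DataFrame whose columns are the instrument's message ids in
    category-major order and whose rows follow the respondent's vignette order.
    """
    import pandas as pd

    if respondent_id not in book.vignettes:
        raise DesignError(f"unknown respondent {respondent_id!r}")
    ids = book.instrument.message_ids
    col = {m: i for i, m in enumerate(ids)}
    vlist = book.vignettes[respondent_id]
    X = np.zeros((len(vlist), len(ids)))
    for i, v in enumerate(vlist):
        for m in v.members:
            X[i, col[m]] = 1.0
    return pd.DataFrame(X, columns=list(ids),
                        index=np.arange(len(vlist)))


def validate_design(book: DesignBook) -> DesignReport:
    """Check every invariant of a DesignBook and summarize collinearity."""
    lo, hi = book.size_range
    n_params = len(book.instrument.message_ids) + 1
    per: dict[str, RespondentCheck] = {}
    max_corr = 0.0
    n_vig = book.n_vignettes
    for rid, vlist in book.vignettes.items():
        X = design_matrix(book, rid).to_numpy()
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        rank = int(np.linalg.matrix_rank(A))
        counts = X.sum(axis=0)
        sizes_ok = all(lo <= len(v) <= hi for v in vlist)
        per[rid] = RespondentCheck(
            rank=rank,
            full_rank=rank == n_params,
            appearance_min=int(counts.min()),
            appearance_max=int(counts.max()),
            size_ok=sizes_ok,
            n_vignettes_ok=len(vlist) == n_vig,
        )
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 0.0)
        c = float(np.nanmax(np.abs(C))) if np.isfinite(C).any() else 1.0
        max_corr = max(max_corr, c)

    dupes: list[tuple[str, str]] = []
    seen: dict[tuple, str] = {}
    for rid, vlist in book.vignettes.items():
        key = tuple(frozenset(v.members) for v in vlist)
        if key in seen:
            dupes.append((seen[key], rid))
        else:
            seen[key] = rid
    return DesignReport(per_respondent=per, duplicate_respondents=dupes,
                        max_abs_column_correlation=max_corr)


# ---------------------------------------------------------------------------
# serialization


def save_design(book: DesignBook, path: str | Path) -> None:
    """Write a DesignBook as CSV (vignette lists) or JSON (full record)."""
    path = Path(path)
    if path.suffix == ".csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["respondent_id", "vignette_index", "members"])
            for rid, vlist in book.vignettes.items():
                for i, v in enumerate(vlist):
                    w.writerow([rid, i, "|".join(sorted(v.members))])
    elif path.suffix == ".json":
        payload = {
            "seed": book.seed,
            "size_range": list(book.size_range),
            "template": [[list(slot) for slot in row] for row in book.template],
            "respondents": {
                rid: {
                    "vignettes": ["|".join(sorted(v.members)) for v in vlist],
                    "category_perms": {
                        c: list(p)
                        for c, p in book.permutations[rid].category_perms.items()
                    },
                    "vignette_order": list(book.permutations[rid].vignette_order),
                }
                for rid, vlist in book.vignettes.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise DesignError(f"unknown design format {path.suffix!r}")


def load_design(path: str | Path, instrument: Instrument) -> DesignBook:
    """Read a DesignBook written by :func:`save_design`."""
    path = Path(path)
    if path.suffix == ".csv":
        rows: dict[str, dict[int, Vignette]] = {}
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                v = Vignette(frozenset(row["members"].split("|")))
                rows.setdefault(row["respondent_id"], {})[int(row["vignette_index"])] = v
        vignettes = {
            rid: [d[i] for i in sorted(d)] for rid, d in rows.items()
        }
        return DesignBook(instrument=instrument, seed=-1, size_range=(2, 4),
                          template=[], vignettes=vignettes)
    if path.suffix == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        vignettes = {}
        perms = {}
        for rid, rec in payload["respondents"].items():
            vignettes[rid] = [
                Vignette(frozenset(s.split("|"))) for s in rec["vignettes"]
            ]
            perms[rid] = PermutationRecord(
                category_perms={c: tuple(p) for c, p in rec["category_perms"].items()},
                vignette_order=tuple(rec["vignette_order"]),
            )
        return DesignBook(
            instrument=instrument, seed=payload["seed"],
            size_range=tuple(payload["size_range"]),
            template=[[tuple(s) for s in row] for row in payload["template"]],
            vignettes=vignettes, permutations=perms,
        )
    raise DesignError(f"unknown design format {path.suffix!r}")
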