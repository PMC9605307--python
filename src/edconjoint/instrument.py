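"""The message instrument: categories of communication messages shown in vignettes.

The default instrument is the 6-category x 6-message inventory of
clinician-patient communication elements for the emergency department
(empathy, information provision, interpersonal skills, comfort,
questions/jargon/role clarity, bedside manner).  Messages are keyed by a
canonical id — category letter plus 1-based index, e.g. ``"C5"`` — and all
downstream tables key on these ids rather than on message texts, which are
free-form and may repeat across categories.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

_ID_RE = re.compile(r"^([A-Z])([1-9][0-9]*)$")

DEFAULT_N_CATEGORIES = 6
DEFAULT_MESSAGES_PER_CATEGORY = 6


class InstrumentError(ValueError):
    """Raised when an instrument file or object violates its invariants."""


@dataclass(frozen=True)
class Message:
    """A single communication message.

    Parameters
    ----------
    id : str
        Category letter plus 1-based within-category index (``"A1"``..``"F6"``
        for the default 6x6 shape).
    category : str
        Human-readable category label.
    text : str
        The message wording shown to respondents.
    """

    id: str
    category: str
    text: str

    def __post_init__(self) -> None:
        m = _ID_RE.match(self.id)
        if m is None:
            raise InstrumentError(f"malformed message id {self.id!r}")

    @property
    def category_letter(self) -> str:
        return self.id[0]

    @property
    def index(self) -> int:
        return int(self.id[1:])


@dataclass(frozen=True)
class Instrument:
    """An ordered set of message categories, each with the same number of messages.

    The canonical shape is 6 categories x 6 messages (36 messages, ids A1..F6);
    other n_cat x n_msg shapes are accepted generically.
    """

    categories: tuple[str, ...]
    messages: tuple[Message, ...]
    _by_id: dict[str, Message] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Message] = {}
        for msg in self.messages:
            if msg.id in by_id:
                raise InstrumentError(f"duplicate message id {msg.id!r}")
            by_id[msg.id] = msg
        object.__setattr__(self, "_by_id", by_id)
        self._validate()

    def _validate(self) -> None:
        if not self.categories:
            raise InstrumentError("incomplete instrument: no categories")
        letters = [chr(ord("A") + i) for i in range(len(self.categories))]
        per_cat = Counter(m.category_letter for m in self.messages)
        missing = [L for L in letters if per_cat.get(L, 0) == 0]
        if missing:
            raise InstrumentError(
                f"incomplete instrument: no messages for categories {missing}"
            )
        stray = sorted(set(per_cat) - set(letters))
        if stray:
            raise InstrumentError(
                f"messages reference unknown category letters {stray}"
            )
        counts = {per_cat[L] for L in letters}
        if len(counts) != 1:
            raise InstrumentError(
                "incomplete instrument: unequal category sizes "
                + str({L: per_cat[L] for L in letters})
            )
        n_msg = counts.pop()
        for L in letters:
            idx = sorted(m.index for m in self.messages if m.category_letter == L)
            if idx != list(range(1, n_msg + 1)):
                raise InstrumentError(
                    f"category {L} indices {idx} are not 1..{n_msg}"
                )
        dup_texts = [t for t, c in Counter(m.text for m in self.messages).items() if c > 1]
        if dup_texts:
            logger.warning(
                "instrument contains repeated message text(s): %s", dup_texts
            )

    # -- shape -------------------------------------------------------------
    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def messages_per_category(self) -> int:
        return len(self.messages) // len(self.categories)

    @property
    def message_ids(self) -> tuple[str, ...]:
        """All message ids in category-major order (A1, A2, ... F6)."""
        return tuple(
            f"{chr(ord('A') + c)}{j}"
            for c in range(self.n_categories)
            for j in range(1, self.messages_per_category + 1)
        )

    def __getitem__(self, message_id: str) -> Message:
        return self._by_id[message_id]

    def __contains__(self, message_id: str) -> bool:
        return message_id in self._by_id

    def category_of(self, message_id: str) -> str:
        return self._by_id[message_id].category


def _build(rows: Iterable[dict[str, str]]) -> Instrument:
    rows = list(rows)
    messages = []
    cat_by_letter: dict[str, str] = {}
    for row in rows:
        try:
            msg = Message(id=row["id"].strip(), category=row["category"].strip(),
                          text=row["text"].strip())
        except KeyError as e:
            raise InstrumentError(f"missing column {e}") from None
        messages.append(msg)
        prev = cat_by_letter.setdefault(msg.category_letter, msg.category)
        if prev != msg.category:
            raise InstrumentError(
                f"category letter {msg.category_letter!r} maps to two labels: "
                f"{prev!r} and {msg.category!r}"
            )
    letters = sorted(cat_by_letter)
    categories = tuple(cat_by_letter[L] for L in letters)
    order = {L: i for i, L in enumerate(letters)}
    messages.sort(key=lambda m: (order[m.category_letter], m.index))
    return Instrument(categories=categories, messages=tuple(messages))


def load_instrument(path: str | Path, format: str | None = None) -> Instrument:
    """Read an instrument from CSV (``id,category,text`` header) or JSON.

    ``format`` is inferred from the file suffix when omitted.  Duplicate
    message texts are tolerated with a logged warning; duplicate ids,
    malformed ids, or unequal category sizes raise :class:`InstrumentError`.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            return _build(csv.DictReader(fh))
    if fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        return _build(payload["messages"])
    raise InstrumentError(f"unknown instrument format {fmt!r}")


def save_instrument(instrument: Instrument, path: str | Path,
                    format: str | None = None) -> None:
    """Write an instrument as CSV or JSON (round-trips with load_instrument)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "category", "text"])
            for m in instrument.messages:
                w.writerow([m.id, m.category, m.text])
    elif fmt == "json":
        payload = {
            "categories": list(instrument.categories),
            "messages": [
                {"id": m.id, "category": m.category, "text": m.text}
                for m in instrument.messages
            ],
        }
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        raise InstrumentError(f"unknown instrument format {fmt!r}")


def default_instrument() -> Instrument:
    """The bundled emergency-department communication instrument (6x6)."""
    ref = resources.files("edconjoint") / "data" / "ed_communication_instrument.csv"
    with resources.as_file(ref) as p:
        return load_instrument(p, format="csv")
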