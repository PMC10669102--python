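"""Item banks, content-based pre-selection, and content-admissibility rules.

An :class:`ItemBank` carries the metadata needed by the abbreviation pipeline:
which construct each item measures, whether it is reverse keyed, how it refers
to the romantic partner, whether it opens with a worry stem, and whether it is
a near-duplicate ("twin") of another item.  Candidate short-form solutions are
screened against content rules *after* optimization, mirroring a filter stage
in which inadmissible solutions are simply not considered further.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONSTRUCTS = ("avoidance", "anxiety")
PARTNER_WORDINGS = ("my_partner", "a_partner", "partners", "none")

#: partner wordings that refer ambiguously to "a partner" / "partners"
AMBIGUOUS_WORDINGS = frozenset({"a_partner", "partners"})


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for a single questionnaire item."""

    id: int
    construct: str
    reverse_keyed: bool = False
    partner_wording: str = "my_partner"
    worry_prefix: bool = False
    twin_group: Optional[int] = None
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(
                f"item {self.id}: construct must be one of {CONSTRUCTS}, "
                f"got {self.construct!r}"
            )
        if self.partner_wording not in PARTNER_WORDINGS:
            raise ValueError(
                f"item {self.id}: partner_wording must be one of "
                f"{PARTNER_WORDINGS}, got {self.partner_wording!r}"
            )


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of items with unique ids."""

    items: tuple[ItemMeta, ...]

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate item ids in bank: {sorted(dupes)}")
        # a twin group is only meaningful when shared by at least two items
        groups = Counter(
            it.twin_group for it in self.items if it.twin_group is not None
        )
        lonely = sorted(g for g, c in groups.items() if c < 2)
        if lonely:
            raise ValueError(f"twin_group(s) {lonely} have fewer than 2 members")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(it.id for it in self.items)

    def item(self, item_id: int) -> ItemMeta:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(f"item id {item_id} not in bank")

    def construct_ids(self, construct: str) -> tuple[int, ...]:
        """Ids of the items measuring ``construct``, in bank order."""
        if construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {construct!r}")
        return tuple(it.id for it in self.items if it.construct == construct)

    @property
    def reverse_keyed_ids(self) -> frozenset[int]:
        return frozenset(it.id for it in self.items if it.reverse_keyed)

    def twin_groups(self) -> dict[int, tuple[int, ...]]:
        """Mapping twin-group label -> ids of its members."""
        out: dict[int, list[int]] = {}
        for it in self.items:
            if it.twin_group is not None:
                out.setdefault(it.twin_group, []).append(it.id)
        return {g: tuple(ids) for g, ids in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [it.id for it in self.items],
                "construct": [it.construct for it in self.items],
                "reverse_keyed": [it.reverse_keyed for it in self.items],
                "partner_wording": [it.partner_wording for it in self.items],
                "worry_prefix": [it.worry_prefix for it in self.items],
                "twin_group": [it.twin_group for it in self.items],
                "text": [it.text for it in self.items],
            }
        )


_REQUIRED_FIELDS = ("id", "construct")
_KNOWN_FIELDS = (
    "id",
    "construct",
    "reverse_keyed",
    "partner_wording",
    "worry_prefix",
    "twin_group",
    "text",
)


def _records_to_bank(records: Sequence[dict]) -> ItemBank:
    items = []
    warned_unknown: set[str] = set()
    for rec in records:
        missing = [f for f in _REQUIRED_FIELDS if f not in rec or pd.isna(rec[f])]
        if missing:
            raise ValueError(f"item record {rec!r} missing required {missing}")
        unknown = set(rec) - set(_KNOWN_FIELDS)
        for f in unknown - warned_unknown:
            logger.warning("ignoring unknown item-metadata field %r", f)
        warned_unknown |= unknown
        twin = rec.get("twin_group")
        if twin is not None and pd.isna(twin):
            twin = None
        text = rec.get("text")
        if text is not None and pd.isna(text):
            text = None
        items.append(
            ItemMeta(
                id=int(rec["id"]),
                construct=str(rec["construct"]),
                reverse_keyed=bool(rec.get("reverse_keyed", False)),
                partner_wording=str(rec.get("partner_wording", "my_partner")),
                worry_prefix=bool(rec.get("worry_prefix", False)),
                twin_group=None if twin is None else int(twin),
                text=None if text is None else str(text),
            )
        )
    bank = ItemBank(tuple(items))
    counts = Counter(it.construct for it in bank)
    if len(set(counts.values())) > 1:
        logger.warning("unbalanced constructs in bank: %s", dict(counts))
    return bank


def load_item_bank(path: str | Path) -> ItemBank:
    """Load an :class:`ItemBank` from a CSV or JSON metadata file.

    Unknown columns/keys are ignored with a logged warning; duplicate ids and
    missing required fields raise ``ValueError``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError("JSON item metadata must be a list of objects")
    else:
        frame = pd.read_csv(path)
        records = frame.to_dict("records")
    return _records_to_bank(records)


def save_item_bank(bank: ItemBank, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = bank.to_frame().to_dict("records")
        for rec in records:
            if pd.isna(rec["twin_group"]):
                rec["twin_group"] = None
            if rec["text"] is None or pd.isna(rec["text"]):
                rec["text"] = None
        path.write_text(json.dumps(records, indent=1, ensure_ascii=False))
    else:
        bank.to_frame().to_csv(path, index=False)


def preselect(
    bank: ItemBank, excluded_wordings: Iterable[str] = AMBIGUOUS_WORDINGS
) -> ItemBank:
    """Drop every item whose partner wording is in ``excluded_wordings``.

    This is the content-based pre-selection step: items that refer to the
    partner ambiguously ("a partner", "partners") are removed from the
    candidate pool before optimization.  Order is preserved and the operation
    is idempotent.
    """
    if len(bank) == 0:
        raise ValueError("cannot preselect from an empty bank")
    excluded = set(excluded_wordings)
    unknown = excluded - set(PARTNER_WORDINGS)
    if unknown:
        raise ValueError(f"unknown partner wordings: {sorted(unknown)}")
    kept = tuple(it for it in bank if it.partner_wording not in excluded)
    if not kept:
        raise ValueError("pre-selection removed every item")
    return ItemBank(kept)


@dataclass(frozen=True)
class AdmissibilityRules:
    """Content rules applied to candidate subsets after optimization.

    no_twin_pairs
        reject subsets containing every member of some twin group
        (near-duplicate wordings must not co-occur in a short form).
    max_worry_items
        reject subsets in which more than this many items open with a
        worry stem (repetitive formulations).
    banned_ids
        reject subsets containing any of these ids (items whose content is
        hard to answer for part of the target population).
    """

    no_twin_pairs: bool = True
    max_worry_items: Optional[int] = 3
    banned_ids: frozenset[int] = frozenset({28})

    def __post_init__(self) -> None:
        object.__setattr__(self, "banned_ids", frozenset(self.banned_ids))


DEFAULT_RULES = AdmissibilityRules()


def content_admissible(
    subset: Iterable[int],
    bank: ItemBank,
    rules: AdmissibilityRules = DEFAULT_RULES,
) -> tuple[bool, list[str]]:
    """Check a candidate subset against the content rules.

    Returns ``(admissible, fired_rules)`` where ``fired_rules`` lists the
    labels of every rule the subset violates (empty when admissible).
    Enabling additional rules can only shrink the admissible set.
    """
    subset = set(subset)
    known = set(bank.ids)
    unknown = subset - known
    if unknown:
        raise KeyError(f"unknown item ids {sorted(unknown)}")
    fired: list[str] = []
    if rules.no_twin_pairs:
        for group, members in bank.twin_groups().items():
            if set(members) <= subset:
                fired.append("twin_pair")
                break
    if rules.max_worry_items is not None:
        n_worry = sum(1 for i in subset if bank.item(i).worry_prefix)
        if n_worry > rules.max_worry_items:
            fired.append("worry_overload")
    if rules.banned_ids & subset:
        fired.append("banned_item")
    return (not fired, fired)
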