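"""Registry of the 21 study-quality checklist items.

The checklist is a hybrid of CAMARADES, Delphi risk-of-bias and GRADE
criteria: 6 binary items (yes/no), 8 tertiary items (yes/no/not clear) and
7 quinary items (na / definitely yes / probably yes / probably no /
definitely no).  The registry ships as packaged JSON; this module exposes it
with the legal responses and point values per response class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

#: Legal response tokens per item class.
RESPONSE_CLASSES: dict[str, tuple[str, ...]] = {
    "binary": ("yes", "no"),
    "tertiary": ("yes", "no", "not_clear"),
    "quinary": ("na", "definitely_yes", "probably_yes", "probably_no", "definitely_no"),
}

#: Points contributed by each response.  ``na`` contributes 0 and does not
#: rescale the total: banding is corpus-relative so an absolute total is all
#: that is needed.
RESPONSE_POINTS: dict[str, float] = {
    "yes": 1.0,
    "no": 0.0,
    "not_clear": 0.5,
    "na": 0.0,
    "definitely_yes": 1.0,
    "probably_yes": 0.75,
    "probably_no": 0.25,
    "definitely_no": 0.0,
}


@dataclass(frozen=True)
class ChecklistItem:
    item_id: str
    label: str
    response_class: str
    sources: tuple[str, ...]

    @property
    def legal_responses(self) -> tuple[str, ...]:
        return RESPONSE_CLASSES[self.response_class]


@lru_cache(maxsize=1)
def checklist_items() -> dict[str, ChecklistItem]:
    """The fixed 21-item registry, keyed by item id."""
    raw = json.loads(
        resources.files("mndprio.data").joinpath("quality_items.json").read_text()
    )
    items = {
        d["item_id"]: ChecklistItem(
            item_id=d["item_id"],
            label=d["label"],
            response_class=d["response_class"],
            sources=tuple(d["sources"]),
        )
        for d in raw["items"]
    }
    classes = [it.response_class for it in items.values()]
    assert len(items) == 21
    assert classes.count("binary") == 6
    assert classes.count("tertiary") == 8
    assert classes.count("quinary") == 7
    return items


def is_legal_response(item_id: str, response: str) -> bool:
    """Whether ``response`` is legal for the class of ``item_id``."""
    item = checklist_items().get(item_id)
    if item is None:
        return False
    return response in item.legal_responses
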