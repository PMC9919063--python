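"""The six question categories used to condition generation."""

from __future__ import annotations

CATEGORIES: tuple[str, ...] = (
    "Abnormality",
    "Modality",
    "Organ",
    "Plane",
    "Position",
    "Others",
)

CATEGORY_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}


def normalize_category(label: str) -> str | None:
    """Case-insensitive match against the six labels; None if unknown."""
    cleaned = label.strip().lower()
    for cat in CATEGORIES:
        if cleaned == cat.lower():
            return cat
    return None
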