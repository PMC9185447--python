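"""The 20-class activity taxonomy used throughout the pipeline.

Sixteen activities of daily living (periodic activities, static postures
and postural transitions) plus four fall types. Class identifiers are
stable small integers (0..19) in the declaration order below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

PERIODIC_STATIC = "periodic/static"
TRANSITION = "transition"
FALL = "fall"

_CLASSES: tuple[tuple[str, str], ...] = (
    ("Walking", PERIODIC_STATIC),
    ("Standing", PERIODIC_STATIC),
    ("Sitting", PERIODIC_STATIC),
    ("Lying", PERIODIC_STATIC),
    ("Upstairs", PERIODIC_STATIC),
    ("Downstairs", PERIODIC_STATIC),
    ("Jumping", PERIODIC_STATIC),
    ("Jogging", PERIODIC_STATIC),
    ("Lying-to-Stand", TRANSITION),
    ("Stand-to-Sit", TRANSITION),
    ("Sit-to-Stand", TRANSITION),
    ("Stand-to-Pick-to-Stand", TRANSITION),
    ("Stand-to-Lying", TRANSITION),
    ("Change-Position-Lying", TRANSITION),
    ("Turning", TRANSITION),
    ("Bending", TRANSITION),
    ("Fall-Forwards", FALL),
    ("Fall-Backwards", FALL),
    ("Fall-Lateral", FALL),
    ("Fall-Syncope", FALL),
)


@dataclass(frozen=True)
class ClassTaxonomy:
    """Ordered 20-label taxonomy with category tags.

    Attributes
    ----------
    names : tuple of str
        Class names in id order (class id = position).
    categories : tuple of str
        Per-class category, one of ``periodic/static``, ``transition``,
        ``fall``.
    """

    names: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 20 or len(self.categories) != 20:
            raise ValueError("taxonomy must have exactly 20 classes")
        n_fall = sum(c == FALL for c in self.categories)
        if n_fall != 4:
            raise ValueError("taxonomy must have exactly 4 fall classes")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def id_of(self, name: str) -> int:
        return self.names.index(name)

    def name_of(self, class_id: int) -> str:
        return self.names[class_id]

    def category_of(self, class_id: int) -> str:
        return self.categories[class_id]

    @property
    def fall_ids(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.categories) if c == FALL)

    def validate_labels(self, labels) -> None:
        """Raise ValueError if any label is outside 0..19."""
        import numpy as np

        arr = np.asarray(labels)
        if arr.size and (arr.min() < 0 or arr.max() >= len(self)):
            raise ValueError("labels outside taxonomy range 0..19")


TAXONOMY = ClassTaxonomy(
    names=tuple(n for n, _ in _CLASSES),
    categories=tuple(c for _, c in _CLASSES),
)

N_CLASSES = len(TAXONOMY)
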