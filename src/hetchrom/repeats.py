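"""Repetitive-element domain types.

Repeat instances carry a family name and one of the fixed repeat class
labels used for C. elegans Dfam-style annotation: DNA transposons
("Cut and paste", "Helitron"), retrotransposons ("LTR", "LINE", "SINE"),
"Satellite", and "Unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval

REPEAT_CLASSES = frozenset(
    {"Cut and paste", "Helitron", "LTR", "LINE", "SINE", "Satellite", "Unknown"}
)


@dataclass(frozen=True)
class RepeatElement:
    """An annotated repeat instance.

    Elements have no stable database identifier; they are named by genomic
    position in the 'chromosome:start-end' convention (see ``name``).
    """

    interval: GenomicInterval
    family: str
    class_label: str
    has_transposase_orf: bool = False
    is_full_length: bool = False

    def __post_init__(self):
        if not self.family:
            raise ValueError("repeat family must be non-empty")
        if self.class_label not in REPEAT_CLASSES:
            raise ValueError(
                f"unknown repeat class {self.class_label!r}; "
                f"expected one of {sorted(REPEAT_CLASSES)}"
            )

    @property
    def name(self) -> str:
        return self.interval.name
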