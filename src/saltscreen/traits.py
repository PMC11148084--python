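"""Trait vocabulary shared across the pipeline.

Six seedling traits are screened at 7 days after sowing (DAS):

========  =======================  ========
code      trait                    units
========  =======================  ========
GR        germination rate         %
RL        root length              cm
SHL       shoot length             cm
SL        seedling length          cm
SFW       seedling fresh weight    mg
SDW       seedling dry weight      mg
========  =======================  ========
"""

from __future__ import annotations

from enum import Enum


class Trait(str, Enum):
    GR = "GR"
    RL = "RL"
    SHL = "SHL"
    SL = "SL"
    SFW = "SFW"
    SDW = "SDW"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical trait order used in tables and reports
ALL_TRAITS: tuple[str, ...] = tuple(t.value for t in Trait)

#: traits entering the regression tolerance model by default (GR excluded)
MODEL_TRAITS: tuple[str, ...] = ("RL", "SHL", "SL", "SFW", "SDW")

#: tolerance grade labels, most tolerant first (used when k = 5)
GRADE_LABELS: tuple[str, ...] = ("HST", "ST", "MST", "SS", "HSS")


def normalize_traits(traits) -> tuple[str, ...]:
    """Coerce an iterable of trait codes/enums to validated string codes."""
    out = []
    for t in traits:
        code = t.value if isinstance(t, Trait) else str(t)
        if code not in ALL_TRAITS:
            raise ValueError(f"unknown trait code {code!r}; expected one of {ALL_TRAITS}")
        out.append(code)
    if not out:
        raise ValueError("trait subset must be non-empty")
    return tuple(out)
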