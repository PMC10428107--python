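"""Domain record types shared across the pipeline.

Sex is coded ``1 = female, 2 = male`` everywhere in the package; the coding
never varies between modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

FEMALE = 1
MALE = 2

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "w": FEMALE, "woman": FEMALE, "1": FEMALE,
    "m": MALE, "male": MALE, "man": MALE, "2": MALE,
}


def normalize_sex(value) -> int:
    """Map a sex label (``F``/``M``/``female``/``male``/1/2 ...) to {1, 2}.

    Raises ``ValueError`` listing the accepted spellings for anything else.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        iv = int(value)
        if iv in (FEMALE, MALE) and iv == value:
            return iv
        raise ValueError(f"sex code {value!r} not in {{1 (female), 2 (male)}}")
    key = str(value).strip().lower()
    if key in _SEX_ALIASES:
        return _SEX_ALIASES[key]
    accepted = sorted(set(_SEX_ALIASES) | {"1", "2"})
    raise ValueError(f"unrecognized sex label {value!r}; accepted: {accepted}")


@dataclass(frozen=True)
class PrintRecord:
    """One measured fingerprint impression.

    Parameters
    ----------
    id : str
        Opaque identifier of the impression.
    mrb : float
        Mean ridge breadth, mm/ridge (> 0).
    n_ridges : int
        Number of ridges averaged in the measurement (>= 1).
    rd : float, optional
        Ridge density, ridges per 25 mm^2 diagonal (> 0 if present).
    category : str, optional
        Artifact class, e.g. ``"figurine"``.
    """

    id: str
    mrb: float
    n_ridges: int
    rd: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self):
        if not self.mrb > 0:
            raise ValueError(f"print {self.id!r}: mrb must be > 0, got {self.mrb}")
        if int(self.n_ridges) != self.n_ridges or self.n_ridges < 1:
            raise ValueError(
                f"print {self.id!r}: n_ridges must be an integer >= 1, got {self.n_ridges}"
            )
        if self.rd is not None and not self.rd > 0:
            raise ValueError(f"print {self.id!r}: rd must be > 0, got {self.rd}")

    def with_mrb(self, mrb: float, rd: Optional[float] = None) -> "PrintRecord":
        return replace(self, mrb=mrb, rd=rd)


@dataclass(frozen=True)
class ReferenceRecord:
    """One individual of a modern reference population (age, sex, MRB)."""

    age: float
    sex: int
    mrb: float

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"reference age must be >= 0, got {self.age}")
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"reference sex must be 1 (female) or 2 (male), got {self.sex}")
        if not self.mrb > 0:
            raise ValueError(f"reference mrb must be > 0, got {self.mrb}")
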