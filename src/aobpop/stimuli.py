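"""Canonical stimulus panel: urine donors identified by sex, strain and status.

The standard panel holds 11 stimuli: urine from males of three strains
(ICR, BALB/C, C57BL/6), each in three virility states (sexually naive,
dominant proven breeder, castrated), plus urine from ICR females in estrus
and non-estrus. Labels are carried as compact string tokens such as
``M_ICR_NAIVE`` or ``F_ICR_EST`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "StimulusLabel",
    "PANEL",
    "PANEL_TOKENS",
    "MALE_STATUSES",
    "FEMALE_STATUSES",
    "STRAINS",
    "parse_label",
    "male_tokens",
    "female_tokens",
]

STRAINS = ("ICR", "BC", "C57")
MALE_STATUSES = ("NAIVE", "DOM", "CAST")
FEMALE_STATUSES = ("NON_EST", "EST")


@dataclass(frozen=True, order=True)
class StimulusLabel:
    """A single urine stimulus identified by donor sex, strain, and status."""

    sex: str      # "M" or "F"
    strain: str   # "ICR", "BC", "C57"
    status: str   # males: NAIVE/DOM/CAST; females: EST/NON_EST

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.sex == "M" and self.status not in MALE_STATUSES:
            raise ValueError(f"invalid male status {self.status!r}")
        if self.sex == "F":
            if self.strain != "ICR":
                raise ValueError("female stimuli are ICR only in the canonical panel")
            if self.status not in FEMALE_STATUSES:
                raise ValueError(f"invalid female status {self.status!r}")

    @property
    def token(self) -> str:
        return f"{self.sex}_{self.strain}_{self.status}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def parse_label(token: str) -> StimulusLabel:
    """Parse a token like ``M_BC_DOM`` or ``F_ICR_NON_EST``."""
    parts = token.strip().upper().split("_")
    if len(parts) < 3:
        raise ValueError(f"malformed stimulus token {token!r}")
    sex, strain = parts[0], parts[1]
    status = "_".join(parts[2:])
    return StimulusLabel(sex=sex, strain=strain, status=status)


#: Canonical 11-stimulus panel, in the column order used by all matrices:
#: the nine males grouped by strain (naive, dominant, castrated within each),
#: then the two females (non-estrus, estrus).
PANEL: tuple[StimulusLabel, ...] = tuple(
    [StimulusLabel("M", strain, status) for strain in STRAINS for status in MALE_STATUSES]
    + [StimulusLabel("F", "ICR", status) for status in FEMALE_STATUSES]
)

PANEL_TOKENS: tuple[str, ...] = tuple(s.token for s in PANEL)


def male_tokens(strain: str | None = None, status: str | None = None) -> list[str]:
    """Male panel tokens, optionally restricted to one strain and/or status."""
    out = []
    for s in PANEL:
        if s.sex != "M":
            continue
        if strain is not None and s.strain != strain:
            continue
        if status is not None and s.status != status:
            continue
        out.append(s.token)
    return out


def female_tokens() -> list[str]:
    return [s.token for s in PANEL if s.sex == "F"]


def validate_panel(tokens: Iterable[str]) -> list[str]:
    """Check that ``tokens`` form the canonical panel; return them in canonical order."""
    seen = {t: parse_label(t).token for t in tokens}
    missing = set(PANEL_TOKENS) - set(seen.values())
    extra = set(seen.values()) - set(PANEL_TOKENS)
    if missing or extra:
        raise ValueError(
            f"stimulus set does not match the canonical 11-label panel; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )
    return list(PANEL_TOKENS)
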