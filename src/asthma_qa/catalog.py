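"""Asthma drug-class catalog and GINA-style severity ranks.

Every prescription record carries an opaque drug code; the catalog maps the
code to a drug class, a controller rank on the 1-4 stepwise-treatment scale,
and (for systemic corticosteroids) a hydrocortisone-equivalent dose per
dispensed unit.  Reliever and exacerbation drugs (SABA, SABA nebulizer,
systemic corticosteroids) carry no rank: they are excluded from severity
scoring.  Oral prednisolone is ranked 4 only when prescribed long-term
(``days_supplied >= LONG_TERM_DAYS``); short courses are treated as
exacerbation bursts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

# Drug class labels.
LOW_ICS = "low-dose ICS"
HIGH_ICS = "high-dose ICS"
LTRA = "LTRA"
XANTHINE = "xanthine"
LABA = "LABA"
LOW_ICS_LABA = "low-dose ICS/LABA"
HIGH_ICS_LABA = "high-dose ICS/LABA"
LAMA = "LAMA"
ORAL_PRED = "low-dose oral prednisolone"
SABA = "SABA"
SABA_NEB = "SABA-nebulizer"
SYS_STEROID = "systemic corticosteroid"

#: Controller rank per class; classes absent here never contribute to severity.
CLASS_RANKS: Mapping[str, int] = {
    LOW_ICS: 1,
    LTRA: 1,
    XANTHINE: 1,
    LABA: 1,
    HIGH_ICS: 2,
    LOW_ICS_LABA: 2,
    HIGH_ICS_LABA: 3,
    LAMA: 4,
    ORAL_PRED: 4,  # only when long-term, see DrugCatalog.rank_for
}

ALL_CLASSES = tuple(CLASS_RANKS) + (SABA, SABA_NEB, SYS_STEROID)

#: Classes that count as "using ICS" for the quality indicators.
ICS_CLASSES = frozenset({LOW_ICS, HIGH_ICS, LOW_ICS_LABA, HIGH_ICS_LABA})

#: Classes whose dose is convertible to hydrocortisone equivalents.
SYSTEMIC_STEROID_CLASSES = frozenset({SYS_STEROID, ORAL_PRED})

#: Classes counted as SABA for indicator (6).
SABA_CLASSES = frozenset({SABA, SABA_NEB})

#: Oral corticosteroid classes for indicator (7).
ORAL_STEROID_CLASSES = frozenset({ORAL_PRED, SYS_STEROID})

#: Anti-inflammatory potency relative to hydrocortisone (editable).
STEROID_POTENCY: Mapping[str, float] = {
    "hydrocortisone": 1.0,
    "prednisolone": 4.0,
    "prednisone": 4.0,
    "methylprednisolone": 5.0,
    "triamcinolone": 5.0,
    "dexamethasone": 25.0,
    "betamethasone": 25.0,
}

#: days_supplied at or above which oral prednisolone counts as a controller.
LONG_TERM_DAYS = 28


@dataclass(frozen=True)
class DrugEntry:
    code: str
    drug_class: str
    hc_equiv_mg: Optional[float] = None  # per dispensed unit, systemic steroids only

    def __post_init__(self) -> None:
        if self.drug_class not in ALL_CLASSES:
            raise ValueError(f"unknown drug class {self.drug_class!r}")
        if self.drug_class in SYSTEMIC_STEROID_CLASSES and self.hc_equiv_mg is None:
            raise ValueError(
                f"{self.code}: systemic corticosteroids need hc_equiv_mg"
            )


class DrugCatalog:
    """Mapping from drug code to class, rank, and steroid potency."""

    def __init__(self, entries: Iterable[DrugEntry]):
        self._entries = {e.code: e for e in entries}
        if not self._entries:
            raise ValueError("empty drug catalog")

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def codes(self) -> tuple:
        return tuple(self._entries)

    def entry(self, code: str) -> DrugEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise KeyError(f"drug code {code!r} not in catalog") from None

    def drug_class(self, code: str) -> str:
        return self.entry(code).drug_class

    def rank_for(self, code: str, days_supplied: int) -> int:
        """Severity rank of one prescription; 0 for unranked (reliever) drugs.

        Oral prednisolone is ranked 4 only for long-term courses.
        """
        entry = self.entry(code)
        if entry.drug_class == ORAL_PRED:
            return 4 if days_supplied >= LONG_TERM_DAYS else 0
        return CLASS_RANKS.get(entry.drug_class, 0)

    def hc_equiv_mg(self, code: str) -> float:
        """Hydrocortisone-equivalent mg per unit; error for non-steroids."""
        entry = self.entry(code)
        if entry.drug_class not in SYSTEMIC_STEROID_CLASSES:
            raise ValueError(f"{code} is not a systemic corticosteroid")
        return float(entry.hc_equiv_mg)

    def codes_of(self, classes: Iterable[str]) -> frozenset:
        wanted = frozenset(classes)
        return frozenset(
            c for c, e in self._entries.items() if e.drug_class in wanted
        )

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            c: {"class": e.drug_class, "hc_equiv_mg": e.hc_equiv_mg}
            for c, e in self._entries.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "DrugCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            DrugEntry(code, spec["class"], spec.get("hc_equiv_mg"))
            for code, spec in payload.items()
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["drug_code", "drug_class", "hc_equiv_mg"])
            for c, e in sorted(self._entries.items()):
                w.writerow([c, e.drug_class, "" if e.hc_equiv_mg is None else e.hc_equiv_mg])

    @classmethod
    def default(cls) -> "DrugCatalog":
        """A small synthetic formulary covering every class in the rank table."""
        p = STEROID_POTENCY
        return cls(
            [
                DrugEntry("ICS_BUD_L", LOW_ICS),
                DrugEntry("ICS_BUD_H", HIGH_ICS),
                DrugEntry("LTRA_MONT", LTRA),
                DrugEntry("XAN_THEO", XANTHINE),
                DrugEntry("LABA_SALM", LABA),
                DrugEntry("ICSLABA_L", LOW_ICS_LABA),
                DrugEntry("ICSLABA_H", HIGH_ICS_LABA),
                DrugEntry("LAMA_TIO", LAMA),
                # 5 mg prednisolone tablet
                DrugEntry("OCS_PRED5", ORAL_PRED, hc_equiv_mg=5.0 * p["prednisolone"]),
                DrugEntry("SABA_SALB", SABA),
                DrugEntry("NEB_SALB", SABA_NEB),
                # 4 mg methylprednisolone tablet
                DrugEntry("SYS_MP4", SYS_STEROID, hc_equiv_mg=4.0 * p["methylprednisolone"]),
                # 0.5 mg dexamethasone tablet
                DrugEntry("SYS_DEXA", SYS_STEROID, hc_equiv_mg=0.5 * p["dexamethasone"]),
                # 10 mg hydrocortisone tablet
                DrugEntry("SYS_HC10", SYS_STEROID, hc_equiv_mg=10.0),
            ]
        )
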