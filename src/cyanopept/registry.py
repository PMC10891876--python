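"""Registry of class-diagnostic product ions for cyanopeptide groups.

The registry is deliberately *empirical*: it stores the measured m/z
values reported for each diagnostic ion rather than masses recomputed
from elemental formulas. Several printed ions differ from formula-derived
values by ~1 mDa, and the Val-Ahp pair is not the CH2 homolog of the
Lxx-Ahp pair; such values are kept verbatim and annotated in the shipped
CSV (``data/diagnostic_ions.csv``), which users can edit or replace to
extend the rules.

Group logic encoded here:

* microcystin  - both Adda fragments (135.0803, 163.1113) required.
* anabaenopeptin - the lysine-related ion 84.0814 required *and intense*;
  exo-residue subclasses from 201.0985+175.1192 (Arg, both required) or a
  single aromatic immonium ion (Trp/Apa/Ahppa).
* cyanopeptolin - group membership via one residue-3/Ahp ion *pair*
  (both members required): Thr, Lxx, Phe or Val.
* aeruginosin  - both Choi ions (140.1064, 122.0962) required; position-2
  subclass from the Hpla-Phe/Hpla-Tyr ions, with chlorinated variants as
  dedicated evidence ions.
* microviridin - no fixed product ions; recognised by precursor charge
  >= 2, neutral mass 1600-1900 Da and >= 2 amino-acid immonium ions from
  the standard immonium table (``data/immonium_ions.csv``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

CYANOPEPTIDE_GROUPS = (
    "aeruginosin",
    "anabaenopeptin",
    "cyanopeptolin",
    "microcystin",
    "microviridin",
)

#: neutral-mass window (Da) of microviridins, observed as 2+/3+ precursors
MICROVIRIDIN_MASS_RANGE = (1600.0, 1900.0)


@dataclass(frozen=True)
class DiagnosticIon:
    """One diagnostic product ion: empirical m/z, a human label, and a role."""

    mz: float
    label: str
    role: str = "required"  # required | required_intense | subclass | chlorine_evidence

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"diagnostic ion m/z must be positive: {self.label}")


@dataclass
class GroupRule:
    """Diagnostic-ion logic for one cyanopeptide group."""

    group: str
    required: tuple[DiagnosticIon, ...] = ()
    intense_required: tuple[DiagnosticIon, ...] = ()
    subclasses: dict[str, tuple[DiagnosticIon, ...]] = field(default_factory=dict)
    chlorine_evidence: dict[str, DiagnosticIon] = field(default_factory=dict)
    #: group membership requires a fully matched subclass ion set
    subclass_defines_group: bool = False
    #: precursor constraints (microviridin): min charge and neutral-mass window
    min_charge: int = 1
    neutral_mass_range: tuple[float, float] | None = None
    uses_immonium: bool = False

    def all_ions(self) -> list[DiagnosticIon]:
        ions = list(self.required) + list(self.intense_required)
        for ion_set in self.subclasses.values():
            ions.extend(ion_set)
        ions.extend(self.chlorine_evidence.values())
        return ions


class DiagnosticRuleRegistry:
    """Per-group / per-subclass diagnostic product-ion rules.

    Built from two editable CSVs: the diagnostic-ion table (columns
    ``group, subclass, mz, label, role``) and the amino-acid immonium
    table (``residue, mz``) used for microviridin recognition.
    """

    def __init__(
        self, groups: Mapping[str, GroupRule], immonium: Mapping[str, float]
    ) -> None:
        self.groups = dict(groups)
        self.immonium = dict(immonium)
        self._validate()

    def _validate(self) -> None:
        for rule in self.groups.values():
            seen: set[float] = set()
            for ion in rule.all_ions():
                key = round(ion.mz, 4)
                if key in seen and ion.role != "chlorine_evidence":
                    raise ValueError(
                        f"duplicate anchor ion {ion.mz} in group {rule.group}"
                    )
                seen.add(key)
        for residue, mz in self.immonium.items():
            if not mz > 0:
                raise ValueError(f"immonium mass must be positive ({residue})")

    def __contains__(self, group: str) -> bool:
        return group in self.groups

    def rule(self, group: str) -> GroupRule:
        if group not in self.groups:
            raise KeyError(f"unknown cyanopeptide group: {group!r}")
        return self.groups[group]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        ions_path: str | Path | None = None,
        immonium_path: str | Path | None = None,
    ) -> "DiagnosticRuleRegistry":
        ions_rows = _read_csv_rows(ions_path, "diagnostic_ions.csv")
        immonium_rows = _read_csv_rows(immonium_path, "immonium_ions.csv")
        immonium = {r["residue"]: float(r["mz"]) for r in immonium_rows}

        groups: dict[str, GroupRule] = {}
        for row in ions_rows:
            group = row["group"].strip()
            subclass = (row.get("subclass") or "").strip() or None
            ion = DiagnosticIon(
                mz=float(row["mz"]), label=row["label"].strip(), role=row["role"].strip()
            )
            rule = groups.setdefault(group, GroupRule(group=group))
            if ion.role == "required":
                rule.required += (ion,)
            elif ion.role == "required_intense":
                rule.intense_required += (ion,)
            elif ion.role == "subclass":
                if subclass is None:
                    raise ValueError(f"subclass ion without subclass label: {ion.label}")
                rule.subclasses[subclass] = rule.subclasses.get(subclass, ()) + (ion,)
            elif ion.role == "chlorine_evidence":
                if subclass is None:
                    raise ValueError(
                        f"chlorine-evidence ion without subclass label: {ion.label}"
                    )
                rule.chlorine_evidence[subclass] = ion
            else:
                raise ValueError(f"unknown ion role {ion.role!r} ({ion.label})")

        if "cyanopeptolin" in groups:
            groups["cyanopeptolin"].subclass_defines_group = True
        # microviridins carry no fixed product ions; the rule is structural
        groups.setdefault("microviridin", GroupRule(group="microviridin"))
        groups["microviridin"].min_charge = 2
        groups["microviridin"].neutral_mass_range = MICROVIRIDIN_MASS_RANGE
        groups["microviridin"].uses_immonium = True
        return cls(groups, immonium)

    @classmethod
    def default(cls) -> "DiagnosticRuleRegistry":
        """The registry shipped with the package."""
        return cls.from_csv()

    def protected_mzs(self) -> list[float]:
        """All diagnostic and immonium m/z values (used e.g. to keep
        synthetic noise peaks away from real landmarks)."""
        mzs = [ion.mz for rule in self.groups.values() for ion in rule.all_ions()]
        mzs.extend(self.immonium.values())
        return sorted(set(mzs))


def _read_csv_rows(path: str | Path | None, default_name: str) -> list[dict]:
    if path is None:
        ref = resources.files("cyanopept.data").joinpath(default_name)
        with ref.open("r", encoding="utf-8") as handle:
            return list(csv.DictReader(handle))
    with open(path, "r", encoding="utf-8") as handle:
        return list(csv.DictReader(handle))


_default_registry: DiagnosticRuleRegistry | None = None


def default_registry() -> DiagnosticRuleRegistry:
    """Module-level cached default registry."""
    global _default_registry
    if _default_registry is None:
        _default_registry = DiagnosticRuleRegistry.default()
    return _default_registry
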