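"""Diagnostic fragment-ion classification of cyanopeptide MS/MS spectra.

Each spectrum is scored against the empirical product-ion registry: a
group is assigned when its required-ion logic holds, the subclass from
the matching subclass ion set, chlorination from the MS1 isotope pattern
(or from a dedicated Cl-evidence product ion), and new cyanopeptolins are
named systematically from their Ahp subclass, integer neutral mass and
elution order.

Ion matching is ppm-based (default 10 ppm): the registry prints ions to
four decimals without tolerances, and a relative window is what an
Orbitrap's calibration behaviour actually implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import Peak, Spectrum
from .registry import DiagnosticRuleRegistry, GroupRule, default_registry


@dataclass
class ClassifierConfig:
    """Tunable matching parameters.

    tol_ppm
        Relative matching tolerance for product ions.
    intense_fraction
        Minimum relative intensity (fraction of the base peak) for the
        anabaenopeptin lysine-related ion, which must be *intense*.
    cl_ratio_window_1 / cl_ratio_window_2
        Accepted M+2/M windows for one and two chlorines (pure-isotope
        expectations: 0.320 and 0.639).
    immonium_min_count
        Minimum distinct amino-acid immonium matches for microviridins.
    """

    tol_ppm: float = 10.0
    intense_fraction: float = 0.2
    cl_ratio_window_1: tuple[float, float] = (0.20, 0.45)
    cl_ratio_window_2: tuple[float, float] = (0.55, 0.85)
    immonium_min_count: int = 2

    def __post_init__(self) -> None:
        if not self.tol_ppm > 0:
            raise ValueError("tol_ppm must be positive")
        if not 0 < self.intense_fraction <= 1:
            raise ValueError("intense_fraction must be in (0, 1]")


@dataclass(frozen=True)
class IonMatch:
    """A matched diagnostic ion with its signed mass error."""

    label: str
    target_mz: float
    observed_mz: float
    intensity: float
    ppm_error: float


@dataclass
class Classification:
    """Outcome for one spectrum."""

    spectrum_id: str
    group: str = "unclassified"
    subclass: str | None = None
    matched_ions: tuple[IonMatch, ...] = ()
    chlorine_count: int = 0
    ambiguous: bool = False
    evidence: dict[str, int] = field(default_factory=dict)
    name: str | None = None

    @property
    def is_cyanopeptide(self) -> bool:
        return self.group != "unclassified"


def match_ion(
    spectrum: Spectrum, target_mz: float, tol_ppm: float
) -> IonMatch | None:
    """Most intense peak within ``tol_ppm`` of ``target_mz``, or None."""
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    if not spectrum.peaks:
        return None
    mz = spectrum.mz_array
    intensity = spectrum.intensity_array
    window = target_mz * tol_ppm * 1e-6
    mask = np.abs(mz - target_mz) <= window
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(intensity[idx])]
    observed = float(mz[best])
    return IonMatch(
        label=f"{target_mz:.4f}",
        target_mz=target_mz,
        observed_mz=observed,
        intensity=float(intensity[best]),
        ppm_error=(observed - target_mz) / target_mz * 1e6,
    )


def _match_registry_ion(spectrum: Spectrum, ion, tol_ppm: float) -> IonMatch | None:
    m = match_ion(spectrum, ion.mz, tol_ppm)
    if m is None:
        return None
    return IonMatch(ion.label, ion.mz, m.observed_mz, m.intensity, m.ppm_error)


@dataclass
class _GroupEvidence:
    group: str
    holds: bool
    n_required_matched: int
    matches: tuple[IonMatch, ...]
    subclass: str | None = None
    subclass_ambiguous: bool = False
    chlorine_from_ms2: bool = False


def _evaluate_group(
    spectrum: Spectrum, rule: GroupRule, registry: DiagnosticRuleRegistry,
    config: ClassifierConfig,
) -> _GroupEvidence:
    matches: list[IonMatch] = []
    n_required = 0
    holds = True

    for ion in rule.required:
        m = _match_registry_ion(spectrum, ion, config.tol_ppm)
        if m is None:
            holds = False
        else:
            matches.append(m)
            n_required += 1
    base = spectrum.base_peak_intensity
    for ion in rule.intense_required:
        m = _match_registry_ion(spectrum, ion, config.tol_ppm)
        if m is None or base <= 0 or m.intensity < config.intense_fraction * base:
            holds = False
        else:
            matches.append(m)
            n_required += 1

    # structural constraints (microviridin)
    if rule.min_charge > 1 and spectrum.charge < rule.min_charge:
        holds = False
    if rule.neutral_mass_range is not None:
        lo, hi = rule.neutral_mass_range
        if not (lo <= spectrum.neutral_mass <= hi):
            holds = False
    if rule.uses_immonium:
        imm_matches = []
        for residue, mz in sorted(registry.immonium.items()):
            m = match_ion(spectrum, mz, config.tol_ppm)
            if m is not None:
                imm_matches.append(
                    IonMatch(f"{residue} immonium", mz, m.observed_mz, m.intensity,
                             m.ppm_error)
                )
        if len(imm_matches) < config.immonium_min_count:
            holds = False
        matches.extend(imm_matches)
        n_required += len(imm_matches)

    # subclass ion sets: every ion of a set must match
    subclass_hits: dict[str, tuple[IonMatch, ...]] = {}
    for subclass, ions in rule.subclasses.items():
        sub_matches = [_match_registry_ion(spectrum, ion, config.tol_ppm) for ion in ions]
        if all(m is not None for m in sub_matches):
            subclass_hits[subclass] = tuple(m for m in sub_matches if m is not None)

    chlorine_from_ms2 = False
    for subclass, ion in rule.chlorine_evidence.items():
        m = _match_registry_ion(spectrum, ion, config.tol_ppm)
        if m is not None:
            # a Cl-shifted subclass ion stands in for the unmodified one
            subclass_hits.setdefault(subclass, (m,))
            matches.append(m)
            chlorine_from_ms2 = True

    subclass = None
    subclass_ambiguous = False
    if subclass_hits:
        if len(subclass_hits) > 1:
            subclass_ambiguous = True
        # deterministic pick: highest summed matched intensity, then name
        subclass = max(
            subclass_hits,
            key=lambda s: (sum(m.intensity for m in subclass_hits[s]), s),
        )
        matches.extend(
            m for m in subclass_hits[subclass] if m not in matches
        )

    if rule.subclass_defines_group:
        if subclass is None:
            holds = False
        else:
            n_required += len(subclass_hits[subclass])

    return _GroupEvidence(
        group=rule.group,
        holds=holds,
        n_required_matched=n_required,
        matches=tuple(matches),
        subclass=subclass,
        subclass_ambiguous=subclass_ambiguous,
        chlorine_from_ms2=chlorine_from_ms2,
    )


def classify_spectrum(
    spectrum: Spectrum,
    registry: DiagnosticRuleRegistry | None = None,
    config: ClassifierConfig | None = None,
) -> Classification:
    """Assign a cyanopeptide group (and subclass) to one MS/MS spectrum.

    Every group rule is evaluated; when several hold, the group with the
    most matched required ions wins and ties set the ambiguous flag (the
    alphabetically first group is reported, all candidates in evidence).
    A spectrum matching no rule is returned as "unclassified".
    """
    if not spectrum.peaks:
        raise ValueError(f"spectrum {spectrum.id} has no peaks")
    registry = registry or default_registry()
    config = config or ClassifierConfig()

    evidence = {
        group: _evaluate_group(spectrum, rule, registry, config)
        for group, rule in sorted(registry.groups.items())
    }
    holding = [ev for ev in evidence.values() if ev.holds]
    if not holding:
        return Classification(
            spectrum_id=spectrum.id,
            evidence={g: ev.n_required_matched for g, ev in evidence.items()},
        )
    best_count = max(ev.n_required_matched for ev in holding)
    winners = sorted(
        (ev for ev in holding if ev.n_required_matched == best_count),
        key=lambda ev: ev.group,
    )
    winner = winners[0]
    ambiguous = len(winners) > 1 or winner.subclass_ambiguous
    return Classification(
        spectrum_id=spectrum.id,
        group=winner.group,
        subclass=winner.subclass,
        matched_ions=winner.matches,
        chlorine_count=1 if winner.chlorine_from_ms2 else 0,
        ambiguous=ambiguous,
        evidence={ev.group: ev.n_required_matched for ev in holding},
    )


def detect_chlorination(
    isotope_pattern: Sequence[Peak], config: ClassifierConfig | None = None
) -> int:
    """Chlorine count (0, 1 or 2) from an MS1 M/M+1/M+2 pattern.

    The M+2/M intensity ratio is compared with windows centred on the
    37Cl/35Cl expectations (0.320 per chlorine); ratios outside both
    windows mean no chlorine (the 13C2 satellite of a mid-size peptide
    stays well below 0.2).
    """
    config = config or ClassifierConfig()
    pattern = sorted(isotope_pattern, key=lambda p: p.mz)
    if len(pattern) < 3:
        raise ValueError("isotope pattern must contain M, M+1 and M+2 peaks")
    m0, m2 = pattern[0], pattern[2]
    if m0.intensity <= 0:
        raise ValueError("monoisotopic peak intensity is zero")
    ratio = m2.intensity / m0.intensity
    lo1, hi1 = config.cl_ratio_window_1
    lo2, hi2 = config.cl_ratio_window_2
    if lo1 <= ratio <= hi1:
        return 1
    if lo2 <= ratio <= hi2:
        return 2
    return 0


def diagnostic_fragmentation_filter(
    spectra: Iterable[Spectrum],
    group: str,
    registry: DiagnosticRuleRegistry | None = None,
    config: ClassifierConfig | None = None,
) -> list[Spectrum]:
    """All spectra whose peaks satisfy a group's required-ion logic.

    This is the rescue path for identifications below the feature
    intensity thresholds: it ignores peak areas entirely and looks only
    at the fragmentation evidence.
    """
    registry = registry or default_registry()
    config = config or ClassifierConfig()
    rule = registry.rule(group)  # KeyError for unknown groups
    out = []
    for s in spectra:
        if not s.peaks:
            continue
        if _evaluate_group(s, rule, registry, config).holds:
            out.append(s)
    return out


_SUBCLASS_LETTER = {"Thr": "T", "Lxx": "L", "Phe": "F", "Val": "V"}


class CyanopeptolinNamer:
    """Assigns systematic names "CP <letter><integer mass><elution letter>".

    The letter encodes the residue-3/Ahp subclass (T/L/F/V), the integer
    part of the neutral mass follows, and isobars of the same subclass
    receive elution-order letters (A = earliest retention time). Callers
    must register congeners in elution order; the pipeline sorts by RT
    before naming. Names are unique within one namer instance.
    """

    def __init__(self) -> None:
        self._assigned: dict[tuple[str, int], list[tuple[float, str]]] = {}

    def assign(self, subclass: str, neutral_mass: float, rt: float) -> str:
        if subclass not in _SUBCLASS_LETTER:
            raise ValueError(f"unknown cyanopeptolin subclass: {subclass!r}")
        letter = _SUBCLASS_LETTER[subclass]
        int_mass = math.floor(neutral_mass)
        key = (letter, int_mass)
        isobars = self._assigned.setdefault(key, [])
        if isobars and rt < isobars[-1][0]:
            raise ValueError(
                f"isobars of CP {letter}{int_mass} must be named in elution order "
                f"(got rt {rt} after {isobars[-1][0]})"
            )
        name = f"CP {letter}{int_mass}{chr(ord('A') + len(isobars))}"
        isobars.append((rt, name))
        return name


def name_cyanopeptolin(
    classification: Classification,
    neutral_mass: float,
    rt: float,
    namer: CyanopeptolinNamer,
) -> str:
    """Name a classified cyanopeptolin by subclass, mass and elution order."""
    if classification.group != "cyanopeptolin" or classification.subclass is None:
        raise ValueError(
            "systematic cyanopeptolin names require a cyanopeptolin "
            "classification with a resolved Ahp subclass"
        )
    name = namer.assign(classification.subclass, neutral_mass, rt)
    classification.name = name
    return name


_LXX_ALIASES = {"leu", "ile", "leucine", "isoleucine", "xle", "lxx", "l", "i"}


def annotate_lxx(residue_call: str) -> str:
    """Collapse leucine/isoleucine calls to "Lxx" (indistinguishable by mass)."""
    if residue_call.strip().lower() in _LXX_ALIASES:
        return "Lxx"
    return residue_call
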