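"""Ground-truth-labelled synthetic cyanopeptide experiments.

The generator emulates the design this pipeline is built for: six
Planktothrix strains in quadruplicate culture plus one media blank,
analysed by positive-mode DDA LC-MS/MS. Each synthetic compound belongs
to one of the five cyanopeptide groups, elutes in the 2.2-5.6 min window,
and lands its precursor in the 590-1210 m/z window (microviridins as
2+/3+ precursors of 1600-1900 Da neutral mass). Rendered MS/MS spectra
carry every diagnostic ion of their (group, subclass) from the empirical
registry, a shared per-family fragment backbone (so that molecular
networking has structure to cluster on), compound-specific fragments,
and uniform noise peaks.

Mass error model: the dominant error source on an Orbitrap is per-scan
calibration, so each rendered spectrum draws ONE Gaussian ppm offset
(sigma = ``ppm_sigma``) applied to all of its peaks and its precursor;
the marginal per-ion error is therefore N(0, ppm_sigma) while ions within
a scan move together, exactly as on the instrument.

Every random draw flows through a single seeded generator, so fixtures
reproduce bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .isotopes import isotope_pattern
from .model import (
    C13_DELTA,
    NA_ADDUCT_DELTA,
    PROTON,
    FeatureTable,
    Peak,
    SampleMeta,
    Spectrum,
)
from .registry import (
    CYANOPEPTIDE_GROUPS,
    MICROVIRIDIN_MASS_RANGE,
    DiagnosticRuleRegistry,
    default_registry,
)

#: precursor m/z window of the acquisition (Th)
MZ_WINDOW = (590.0, 1210.0)
#: retention-time window (min)
RT_WINDOW = (2.2, 5.6)


@dataclass(frozen=True)
class CompoundSpec:
    """One ground-truth compound (or non-cyanopeptide decoy metabolite)."""

    compound_id: str
    group: str  # one of CYANOPEPTIDE_GROUPS or "decoy"
    subclass: str | None
    neutral_mass: float
    charge: int
    rt: float
    chlorinated: bool = False
    strain_label: str | None = None
    #: fragment m/z shared by all compounds of the same (group, subclass) family
    backbone_mzs: tuple[float, ...] = ()
    #: compound-specific fragment m/z
    extra_mzs: tuple[float, ...] = ()

    @property
    def precursor_mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge


@dataclass
class StrainSpec:
    """How many compounds of each (group, subclass) one strain produces."""

    strain_label: str
    counts: Mapping[str, Mapping[str | None, int]] = field(default_factory=dict)
    decoy_count: int = 0
    chlorination_fraction: float = 0.0

    def __post_init__(self) -> None:
        for group, subcounts in self.counts.items():
            for subclass, n in subcounts.items():
                if n < 0:
                    raise ValueError(
                        f"negative count for {group}/{subclass} in {self.strain_label}"
                    )
        if not 0 <= self.chlorination_fraction <= 1:
            raise ValueError("chlorination_fraction must be in [0, 1]")


@dataclass
class GeneratorConfig:
    """Noise and design parameters of the synthetic experiment.

    The noise model is the generator's own (configurable, documented in
    the methods note): Gaussian per-scan ppm mass error, lognormal
    compound abundances, lognormal replicate scatter with coefficient of
    variation ``replicate_cv``, uniform-m/z noise peaks, and optional ESI
    redundancy (sodium adducts, 13C isotopologues) plus media-blank
    features.
    """

    seed: int = 0
    ppm_sigma: float = 5.0
    noise_peaks_per_spectrum: int = 10
    intensity_mu: float = 17.0  # ln-scale mean of feature areas (~2.4e7 median)
    intensity_sigma: float = 1.0
    replicate_cv: float = 0.2
    blank_carryover_prob: float = 0.1
    blank_area_fraction: float = 0.01
    adduct_prob: float = 0.15
    isotopologue_prob: float = 0.3
    n_media_features: int = 5
    media_leak_fraction: float = 0.005
    ms2_per_feature: int = 3
    ms2_base_peak_mu: float = 16.5  # ln-scale; median ~1.5e7 counts
    ms2_base_peak_sigma: float = 0.8
    n_backbone_peaks: int = 10
    n_extra_peaks: int = 3
    replicates_per_strain: int = 4
    biomass_range_mg: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        for name in ("blank_carryover_prob", "adduct_prob", "isotopologue_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-feature labels enabling label-recovery tests.

    One row per generated feature: cyanopeptide group (or "decoy" /
    "media"), subclass, chlorination flag, producing strain set, and the
    redundancy role (monoisotopic | adduct | isotopologue | decoy | blank).
    """

    table: pd.DataFrame  # index feature_id; columns group, subclass, chlorinated, strains, role

    def role_of(self, feature_id: str) -> str:
        return str(self.table.loc[feature_id, "role"])

    def features_with_role(self, *roles: str) -> list[str]:
        mask = self.table["role"].isin(roles)
        return list(self.table.index[mask])

    def label_of(self, feature_id: str) -> tuple[str, str | None]:
        row = self.table.loc[feature_id]
        subclass = row["subclass"]
        return str(row["group"]), (None if pd.isna(subclass) else str(subclass))

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["strains"] = out["strains"].map(lambda s: ";".join(sorted(s)))
        out.index.name = "feature_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, index_col="feature_id")
        df["strains"] = df["strains"].fillna("").map(
            lambda s: frozenset(x for x in str(s).split(";") if x)
        )
        df["chlorinated"] = df["chlorinated"].astype(bool)
        return cls(df)


# ---------------------------------------------------------------------------
# compound library


def _draw_family_backbone(rng: np.random.Generator, n: int) -> tuple[float, ...]:
    return tuple(np.sort(rng.uniform(250.0, 560.0, size=n)))


def generate_library(
    strain_specs: Sequence[StrainSpec],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    registry: DiagnosticRuleRegistry | None = None,
) -> list[CompoundSpec]:
    """Draw the ground-truth compound library for an experiment.

    Neutral masses are drawn so precursors land inside the m/z window
    (charge-adjusted); retention times are uniform over the RT window.
    Compounds of the same (group, subclass) family share a fragment
    backbone, mirroring the common core structures within a cyanopeptide
    class. Deterministic under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    registry = registry or default_registry()
    backbones: dict[tuple[str, str | None], tuple[float, ...]] = {}
    library: list[CompoundSpec] = []
    for spec in strain_specs:
        idx = 0
        for group in sorted(spec.counts):
            subcounts = spec.counts[group]
            for subclass in sorted(subcounts, key=lambda s: (s is None, s or "")):
                for _ in range(subcounts[subclass]):
                    idx += 1
                    library.append(
                        _draw_compound(
                            rng,
                            config,
                            backbones,
                            f"{spec.strain_label}_{group[:2]}{idx:03d}",
                            group,
                            subclass,
                            spec,
                        )
                    )
    return library


def _draw_compound(
    rng: np.random.Generator,
    config: GeneratorConfig,
    backbones: dict,
    compound_id: str,
    group: str,
    subclass: str | None,
    spec: StrainSpec,
) -> CompoundSpec:
    if group not in CYANOPEPTIDE_GROUPS:
        raise ValueError(f"unknown cyanopeptide group {group!r}")
    if group == "microviridin":
        charge = 2 if rng.random() > 0.3 else 3
        lo, hi = MICROVIRIDIN_MASS_RANGE
        if charge == 3:
            # keep the 3+ precursor above the low edge of the m/z window
            lo = max(lo, 3 * (MZ_WINDOW[0] - PROTON))
        neutral_mass = float(rng.uniform(lo, hi))
    else:
        charge = 1
        precursor = float(rng.uniform(MZ_WINDOW[0] + 2.0, MZ_WINDOW[1] - 2.0))
        neutral_mass = precursor - PROTON
    chlorinated = bool(
        group == "aeruginosin" and rng.random() < spec.chlorination_fraction
    )
    rt = float(rng.uniform(*RT_WINDOW))
    key = (group, subclass)
    if key not in backbones:
        backbones[key] = _draw_family_backbone(rng, config.n_backbone_peaks)
    compound = CompoundSpec(
        compound_id=compound_id,
        group=group,
        subclass=subclass,
        neutral_mass=neutral_mass,
        charge=charge,
        rt=rt,
        chlorinated=chlorinated,
        strain_label=spec.strain_label,
        backbone_mzs=backbones[key],
        extra_mzs=tuple(rng.uniform(250.0, 560.0, size=config.n_extra_peaks)),
    )
    validate_compound(compound)
    return compound


def validate_compound(compound: CompoundSpec) -> None:
    """Reject compounds whose precursor cannot fall in the acquisition window
    (e.g. a singly charged microviridin)."""
    if compound.group == "decoy":
        return
    if not MZ_WINDOW[0] <= compound.precursor_mz <= MZ_WINDOW[1]:
        raise ValueError(
            f"infeasible compound {compound.compound_id}: precursor "
            f"{compound.precursor_mz:.4f} outside the acquisition window"
        )


def make_decoy(
    rng: np.random.Generator, config: GeneratorConfig, compound_id: str,
    strain_label: str, registry: DiagnosticRuleRegistry,
) -> CompoundSpec:
    """A non-cyanopeptide metabolite: reproducible fragments, none diagnostic."""
    precursor = float(rng.uniform(550.0, 1250.0))
    fragments = _sample_clear_mzs(rng, registry, 8, 100.0, min(precursor, 560.0) + 1)
    return CompoundSpec(
        compound_id=compound_id,
        group="decoy",
        subclass=None,
        neutral_mass=precursor - PROTON,
        charge=1,
        rt=float(rng.uniform(*RT_WINDOW)),
        strain_label=strain_label,
        extra_mzs=tuple(fragments),
    )


def _sample_clear_mzs(
    rng: np.random.Generator,
    registry: DiagnosticRuleRegistry,
    n: int,
    lo: float,
    hi: float,
    clearance_ppm: float = 25.0,
) -> list[float]:
    """Uniform m/z draws rejected near any registry/immonium landmark."""
    protected = np.asarray(registry.protected_mzs())
    out: list[float] = []
    while len(out) < n:
        mz = float(rng.uniform(lo, hi))
        if np.min(np.abs(protected - mz)) > mz * clearance_ppm * 1e-6:
            out.append(mz)
    return out


# ---------------------------------------------------------------------------
# spectrum rendering


def _diagnostic_mzs(
    compound: CompoundSpec, registry: DiagnosticRuleRegistry,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """(m/z, relative intensity) of the diagnostic ions this compound must show."""
    rule = registry.rule(compound.group)
    out: list[tuple[float, float]] = []
    for ion in rule.required:
        out.append((ion.mz, float(rng.uniform(0.4, 1.0))))
    for ion in rule.intense_required:
        # the lysine-related ion of anabaenopeptins is rendered intense
        out.append((ion.mz, float(rng.uniform(0.5, 1.0))))
    if compound.subclass is not None:
        if compound.chlorinated and compound.subclass in rule.chlorine_evidence:
            # chlorinated Hpla shifts the position-2 ion to its Cl form
            out.append(
                (rule.chlorine_evidence[compound.subclass].mz, float(rng.uniform(0.3, 1.0)))
            )
        else:
            for ion in rule.subclasses[compound.subclass]:
                out.append((ion.mz, float(rng.uniform(0.3, 1.0))))
    if rule.uses_immonium:
        residues = sorted(registry.immonium)
        picks = rng.choice(len(residues), size=4, replace=False)
        for k in sorted(picks):
            out.append((registry.immonium[residues[k]], float(rng.uniform(0.4, 1.0))))
    return out


def render_spectrum(
    compound: CompoundSpec,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    registry: DiagnosticRuleRegistry | None = None,
    spectrum_id: str | None = None,
    sample_id: str | None = None,
    is_seed: bool = False,
    observed_precursor_mz: float | None = None,
) -> Spectrum:
    """Render one MS/MS spectrum of a compound.

    The spectrum contains every diagnostic ion of the compound's (group,
    subclass) at its registry m/z perturbed by the scan's shared Gaussian
    ppm offset, the family backbone and compound-specific fragments, and
    ``noise_peaks_per_spectrum`` noise peaks at random m/z below the
    precursor (kept clear of registry landmarks, so decoys contain no
    diagnostic ion within matching tolerance by construction).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    registry = registry or default_registry()
    scan_offset = float(rng.normal(0.0, config.ppm_sigma)) if config.ppm_sigma else 0.0
    scale = 1.0 + scan_offset * 1e-6

    signal: list[tuple[float, float]] = []
    if compound.group != "decoy":
        signal.extend(_diagnostic_mzs(compound, registry, rng))
    for mz in compound.backbone_mzs:
        signal.append((mz, float(rng.uniform(0.3, 1.0))))
    for mz in compound.extra_mzs:
        signal.append((mz, float(rng.uniform(0.2, 0.8))))

    precursor = (
        observed_precursor_mz
        if observed_precursor_mz is not None
        else compound.precursor_mz * scale
    )
    peaks = [(mz * scale, rel) for mz, rel in signal]
    if config.noise_peaks_per_spectrum:
        noise_mzs = _sample_clear_mzs(
            rng, registry, config.noise_peaks_per_spectrum, 100.0, max(precursor, 101.0)
        )
        for mz in noise_mzs:
            rel = min(0.9, 0.1 * float(rng.lognormal(0.0, 0.8)))
            peaks.append((mz, rel))

    base = float(rng.lognormal(config.ms2_base_peak_mu, config.ms2_base_peak_sigma))
    top = max(rel for _, rel in peaks)
    return Spectrum(
        id=spectrum_id or f"{compound.compound_id}__ms2",
        precursor_mz=precursor,
        charge=compound.charge,
        rt=compound.rt,
        peaks=tuple(Peak(mz, rel / top * base) for mz, rel in peaks),
        sample_id=sample_id,
        is_seed=is_seed,
    )


def render_isotope_pattern(compound: CompoundSpec) -> list[Peak]:
    """MS1 isotope pattern (M, M+1, M+2) of a compound; see `isotopes`."""
    return isotope_pattern(
        compound.precursor_mz,
        compound.neutral_mass,
        charge=compound.charge,
        n_cl=1 if compound.chlorinated else 0,
    )


# ---------------------------------------------------------------------------
# experiment assembly


def simulate_experiment(
    strain_specs: Sequence[StrainSpec],
    config: GeneratorConfig,
    registry: DiagnosticRuleRegistry | None = None,
) -> tuple[FeatureTable, list[Spectrum], GroundTruth]:
    """Simulate a full quadruplicate-culture experiment.

    Returns the rectangular feature table (replicates of every strain
    plus one media blank), the DDA MS/MS spectra (``ms2_per_feature``
    scans per compound feature, taken in the replicates with the largest
    areas), and the ground-truth labels. ESI-redundant features (sodium
    adducts at +21.9819 for 1+ species, 13C isotopologues at +1.00336/z)
    co-elute with their parent and are labelled with their role, as are
    media-blank features and decoys.
    """
    if not strain_specs:
        raise ValueError("at least one strain is required")
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    library = generate_library(strain_specs, config, rng, registry)

    samples: list[SampleMeta] = []
    strain_to_samples: dict[str, list[str]] = {}
    for spec in strain_specs:
        ids = []
        for r in range(1, config.replicates_per_strain + 1):
            sid = f"{spec.strain_label}_r{r}"
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    strain_label=spec.strain_label,
                    replicate_index=r,
                    dry_biomass_mg=float(rng.uniform(*config.biomass_range_mg)),
                )
            )
            ids.append(sid)
        strain_to_samples[spec.strain_label] = ids
    blank_id = "blank"
    samples.append(
        SampleMeta(sample_id=blank_id, strain_label="media_blank", replicate_index=1,
                   is_blank=True)
    )
    sample_ids = [s.sample_id for s in samples]

    rep_sigma = math.sqrt(math.log(1.0 + config.replicate_cv**2))

    rows: list[dict] = []  # feature records
    truth_rows: list[dict] = []
    spectra: list[Spectrum] = []
    ms2_links: dict[str, list[str]] = {}

    def add_feature(fid, mz, rt, areas, group, subclass, chlorinated, strains, role):
        rows.append({"feature_id": fid, "mz": mz, "rt": rt, **areas})
        truth_rows.append(
            {
                "feature_id": fid,
                "group": group,
                "subclass": subclass,
                "chlorinated": chlorinated,
                "strains": frozenset(strains),
                "role": role,
            }
        )

    def replicate_areas(mean_area: float, strain: str) -> dict[str, float]:
        areas = {sid: 0.0 for sid in sample_ids}
        for sid in strain_to_samples[strain]:
            areas[sid] = mean_area * float(rng.lognormal(-rep_sigma**2 / 2, rep_sigma))
        return areas

    for compound in library:
        fid = compound.compound_id
        feat_mz = compound.precursor_mz * (
            1.0 + float(rng.normal(0.0, config.ppm_sigma)) * 1e-6
        )
        mean_area = float(rng.lognormal(config.intensity_mu, config.intensity_sigma))
        areas = replicate_areas(mean_area, compound.strain_label)
        if rng.random() < config.blank_carryover_prob:
            areas[blank_id] = config.blank_area_fraction * mean_area
        add_feature(
            fid, feat_mz, compound.rt, areas, compound.group, compound.subclass,
            compound.chlorinated, {compound.strain_label}, "monoisotopic",
        )

        if rng.random() < config.isotopologue_prob:
            frac = float(rng.uniform(0.25, 0.5))
            iso_areas = {
                sid: (a * frac if sid != blank_id else 0.0) for sid, a in areas.items()
            }
            add_feature(
                f"{fid}_i13", feat_mz + C13_DELTA / compound.charge, compound.rt,
                iso_areas, compound.group, compound.subclass, compound.chlorinated,
                {compound.strain_label}, "isotopologue",
            )
        if compound.charge == 1 and rng.random() < config.adduct_prob:
            frac = float(rng.uniform(0.1, 0.4))
            na_areas = {
                sid: (a * frac if sid != blank_id else 0.0) for sid, a in areas.items()
            }
            add_feature(
                f"{fid}_na", feat_mz + NA_ADDUCT_DELTA, compound.rt, na_areas,
                compound.group, compound.subclass, compound.chlorinated,
                {compound.strain_label}, "adduct",
            )

        # DDA MS/MS in the replicates with the largest areas
        reps = strain_to_samples[compound.strain_label]
        order = sorted(reps, key=lambda sid: -areas[sid])
        for k, sid in enumerate(order[: config.ms2_per_feature]):
            spectrum = render_spectrum(
                compound, config, rng, registry,
                spectrum_id=f"{fid}__s{k}", sample_id=sid,
                observed_precursor_mz=feat_mz,
            )
            spectra.append(spectrum)
            ms2_links.setdefault(fid, []).append(spectrum.id)

    # non-cyanopeptide decoy metabolites
    for spec in strain_specs:
        for d in range(spec.decoy_count):
            decoy = make_decoy(
                rng, config, f"{spec.strain_label}_dx{d:03d}", spec.strain_label, registry
            )
            fid = decoy.compound_id
            mean_area = float(rng.lognormal(config.intensity_mu, config.intensity_sigma))
            areas = replicate_areas(mean_area, spec.strain_label)
            add_feature(
                fid, decoy.precursor_mz, decoy.rt, areas, "decoy", None, False,
                {spec.strain_label}, "decoy",
            )
            reps = sorted(strain_to_samples[spec.strain_label], key=lambda s: -areas[s])
            for k, sid in enumerate(reps[: config.ms2_per_feature]):
                spectrum = render_spectrum(
                    decoy, config, rng, registry,
                    spectrum_id=f"{fid}__s{k}", sample_id=sid,
                    observed_precursor_mz=decoy.precursor_mz,
                )
                spectra.append(spectrum)
                ms2_links.setdefault(fid, []).append(spectrum.id)

    # media-blank features: strong in the blank, trace leakage into samples
    for m in range(config.n_media_features):
        fid = f"media{m:03d}"
        blank_area = float(
            rng.lognormal(config.intensity_mu + 1.0, config.intensity_sigma)
        )
        areas = {
            sid: blank_area * config.media_leak_fraction * float(rng.uniform(0.5, 1.5))
            for sid in sample_ids
        }
        areas[blank_id] = blank_area
        add_feature(
            fid, float(rng.uniform(*MZ_WINDOW)), float(rng.uniform(*RT_WINDOW)),
            areas, "media", None, False, set(), "blank",
        )

    features_df = pd.DataFrame(rows).set_index("feature_id")
    meta = pd.DataFrame(
        {
            "strain_label": [s.strain_label for s in samples],
            "replicate_index": [s.replicate_index for s in samples],
            "is_blank": [s.is_blank for s in samples],
            "dry_biomass_mg": [s.dry_biomass_mg for s in samples],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(
        features_df[sample_ids], features_df[["mz", "rt"]], meta, ms2_links
    )
    truth = GroundTruth(pd.DataFrame(truth_rows).set_index("feature_id"))
    return table, spectra, truth


def make_seed_spectra(
    compounds: Sequence[CompoundSpec],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    registry: DiagnosticRuleRegistry | None = None,
) -> list[Spectrum]:
    """Render reference (seed) spectra for the molecular network."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    return [
        render_spectrum(
            c, config, rng, registry,
            spectrum_id=f"seed_{c.compound_id}", sample_id="seed", is_seed=True,
        )
        for c in compounds
    ]


# ---------------------------------------------------------------------------
# default scenario: six strains in quadruplicate, one media blank


def default_strain_specs() -> list[StrainSpec]:
    """The default six-strain scenario.

    Group counts per strain mirror the published distribution of detected
    cyanopeptides across six Planktothrix CPCC strains; subclass splits
    within groups follow the qualitative pattern reported there (three
    strains produce exclusively Thr-Ahp cyanopeptolins, two produce
    Lxx/Phe/Val congeners, aeruginosins are restricted to two strains with
    chlorination in one of them). Each strain also yields a few
    non-cyanopeptide decoy metabolites.
    """
    ap = lambda arg, trp, apa, ahppa: {
        "exo-Arg": arg, "exo-Trp": trp, "exo-Apa": apa, "exo-Ahppa": ahppa
    }
    return [
        StrainSpec(
            "CPCC 507",
            {
                "cyanopeptolin": {"Thr": 31},
                "anabaenopeptin": ap(0, 6, 5, 5),
                "microviridin": {None: 11},
                "microcystin": {None: 8},
            },
            decoy_count=3,
        ),
        StrainSpec(
            "CPCC 720",
            {
                "cyanopeptolin": {"Thr": 28},
                "anabaenopeptin": ap(2, 3, 3, 2),
                "microviridin": {None: 17},
                "microcystin": {None: 4},
            },
            decoy_count=3,
        ),
        StrainSpec(
            "CPCC 731",
            {
                "cyanopeptolin": {"Lxx": 7, "Phe": 5, "Val": 5},
                "anabaenopeptin": ap(3, 4, 4, 3),
                "aeruginosin": {"Hpla-Phe": 10, "Hpla-Tyr": 9},
                "microcystin": {None: 12},
            },
            decoy_count=3,
        ),
        StrainSpec(
            "CPCC 732",
            {
                "cyanopeptolin": {"Lxx": 5, "Phe": 3, "Val": 3},
                "anabaenopeptin": ap(3, 4, 3, 3),
                "microcystin": {None: 3},
            },
            decoy_count=3,
        ),
        StrainSpec(
            "CPCC 733",
            {
                "anabaenopeptin": ap(8, 10, 8, 8),
                "microviridin": {None: 14},
                "microcystin": {None: 6},
            },
            decoy_count=3,
        ),
        StrainSpec(
            "CPCC 735",
            {
                "cyanopeptolin": {"Thr": 23},
                "anabaenopeptin": ap(3, 3, 3, 3),
                "microviridin": {None: 14},
                "aeruginosin": {"Hpla-Phe": 5, "Hpla-Tyr": 4},
                "microcystin": {None: 10},
            },
            decoy_count=3,
            chlorination_fraction=0.5,
        ),
    ]


def default_seed_compounds(
    library: Sequence[CompoundSpec],
    rng: np.random.Generator,
    n_shared: int = 4,
    n_seed_only: int = 3,
) -> list[CompoundSpec]:
    """Seed compounds for networking: a few compounds shared with the
    extracts (anchoring clusters) plus seed-only standards that end up as
    singletons."""
    cyano = [c for c in library if c.group != "decoy"]
    picks = rng.choice(len(cyano), size=min(n_shared, len(cyano)), replace=False)
    shared = [cyano[int(i)] for i in sorted(picks)]
    seed_only = []
    backbones: dict = {}
    cfg = GeneratorConfig()
    for k in range(n_seed_only):
        seed_only.append(
            _draw_compound(
                rng, cfg, backbones, f"std{k:02d}", "microcystin", None,
                StrainSpec("seed_reference"),
            )
        )
    return shared + seed_only
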