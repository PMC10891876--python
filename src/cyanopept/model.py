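"""Domain types shared across the pipeline.

Mass spectra are represented as centroided peak lists with precursor
metadata; feature tables couple a rectangular peak-area matrix (features x
samples) with per-sample culture metadata (strain, replicate, blank flag,
dry biomass). Retention times are minutes everywhere; m/z values are kept
at full floating precision and only formatted at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: mass of a proton, Da
PROTON = 1.00727646677
#: 13C - 12C mass difference, Da
C13_DELTA = 1.0033548
#: m/z shift of a sodiated species relative to the protonated one (z = 1), Da
NA_ADDUCT_DELTA = 21.981944
#: m/z shift of a potassiated species relative to the protonated one (z = 1), Da
K_ADDUCT_DELTA = 37.955882
#: m/z shift of an ammonium adduct relative to the protonated species (z = 1), Da
NH4_ADDUCT_DELTA = 17.026549

#: instrument survey-scan range used by the acquisition this pipeline models, Th
SCAN_RANGE = (106.7, 1600.0)


@dataclass(frozen=True, order=True)
class Peak:
    """One centroided peak: m/z in Th, intensity in arbitrary counts."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A centroided MS/MS scan.

    Peaks are kept sorted ascending by m/z; ``base_peak_intensity`` is always
    the maximum peak intensity. ``is_seed`` marks reference spectra injected
    into molecular networks to anchor cluster identity.
    """

    id: str
    precursor_mz: float
    charge: int = 1
    rt: float = 0.0
    peaks: tuple[Peak, ...] = ()
    sample_id: str | None = None
    is_seed: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.rt < 0:
            raise ValueError(f"retention time must be >= 0, got {self.rt}")
        if not self.precursor_mz > 0:
            raise ValueError("precursor m/z must be positive")
        self.peaks = tuple(sorted(self.peaks, key=lambda p: (p.mz, p.intensity)))

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass implied by precursor m/z and charge."""
        return self.charge * (self.precursor_mz - PROTON)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one analysed sample (culture replicate or media blank)."""

    sample_id: str
    strain_label: str
    replicate_index: int = 1
    is_blank: bool = False
    dry_biomass_mg: float | None = None

    def __post_init__(self) -> None:
        if self.dry_biomass_mg is not None and not self.dry_biomass_mg > 0:
            raise ValueError(
                f"dry biomass must be positive when present "
                f"(sample {self.sample_id}: {self.dry_biomass_mg})"
            )


@dataclass
class Feature:
    """One deconvoluted MS1 feature with per-sample peak areas."""

    feature_id: str
    mz: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    ms2_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature m/z must be positive ({self.feature_id})")
        for sid, a in self.areas.items():
            if a < 0:
                raise ValueError(f"negative area for {self.feature_id}/{sid}")


_SAMPLE_COLUMNS = ["strain_label", "replicate_index", "is_blank", "dry_biomass_mg"]


class FeatureTable:
    """Rectangular features x samples peak-area matrix plus sample metadata.

    Parameters
    ----------
    areas
        DataFrame indexed by feature id with one column per sample id.
    feature_info
        DataFrame indexed by feature id with columns ``mz`` and ``rt``.
    samples
        DataFrame indexed by sample id with columns ``strain_label``,
        ``replicate_index``, ``is_blank`` and ``dry_biomass_mg``.
    ms2_ids
        Optional mapping feature id -> ids of linked MS/MS spectra.
    """

    def __init__(
        self,
        areas: pd.DataFrame,
        feature_info: pd.DataFrame,
        samples: pd.DataFrame,
        ms2_ids: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if areas.index.duplicated().any():
            dupes = areas.index[areas.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if samples.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if set(areas.columns) != set(samples.index):
            missing = set(areas.columns) - set(samples.index)
            extra = set(samples.index) - set(areas.columns)
            raise ValueError(
                f"area matrix and sample metadata disagree "
                f"(no metadata: {sorted(missing)}; no areas: {sorted(extra)})"
            )
        if not areas.index.equals(feature_info.index):
            feature_info = feature_info.loc[areas.index]
        areas = areas[list(samples.index)].astype(float)
        if (areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas")
        areas.index.name = "feature_id"
        areas.columns.name = "sample_id"
        self.areas = areas
        self.feature_info = feature_info[["mz", "rt"]].astype(float)
        self.samples = samples[_SAMPLE_COLUMNS].copy()
        self.ms2_ids: dict[str, tuple[str, ...]] = {
            fid: tuple(ids) for fid, ids in (ms2_ids or {}).items() if fid in areas.index
        }

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def n_features(self) -> int:
        return self.areas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.areas.shape[1]

    def blank_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["is_blank"].astype(bool)])

    def non_blank_sample_ids(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_blank"].astype(bool)])

    def strain_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "strain_label"])

    def strain_labels(self) -> list[str]:
        """Distinct non-blank strain labels in sample order."""
        labels = self.samples.loc[~self.samples["is_blank"].astype(bool), "strain_label"]
        return list(dict.fromkeys(labels))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, features: Iterable[Feature], samples: Iterable[SampleMeta]
    ) -> "FeatureTable":
        samples = list(samples)
        meta = pd.DataFrame(
            {
                "strain_label": [s.strain_label for s in samples],
                "replicate_index": [s.replicate_index for s in samples],
                "is_blank": [s.is_blank for s in samples],
                "dry_biomass_mg": [s.dry_biomass_mg for s in samples],
            },
            index=pd.Index([s.sample_id for s in samples], name="sample_id"),
        )
        feats = list(features)
        idx = pd.Index([f.feature_id for f in feats], name="feature_id")
        info = pd.DataFrame(
            {"mz": [f.mz for f in feats], "rt": [f.rt for f in feats]}, index=idx
        )
        areas = pd.DataFrame(
            [[f.areas.get(s.sample_id, 0.0) for s in samples] for f in feats],
            index=idx,
            columns=meta.index,
        )
        ms2 = {f.feature_id: tuple(f.ms2_ids) for f in feats if f.ms2_ids}
        return cls(areas, info, meta, ms2)

    def to_records(self) -> tuple[list[Feature], list[SampleMeta]]:
        samples = [
            SampleMeta(
                sample_id=str(sid),
                strain_label=str(row["strain_label"]),
                replicate_index=int(row["replicate_index"]),
                is_blank=bool(row["is_blank"]),
                dry_biomass_mg=None
                if pd.isna(row["dry_biomass_mg"])
                else float(row["dry_biomass_mg"]),
            )
            for sid, row in self.samples.iterrows()
        ]
        feats = [
            Feature(
                feature_id=str(fid),
                mz=float(self.feature_info.loc[fid, "mz"]),
                rt=float(self.feature_info.loc[fid, "rt"]),
                areas=dict(self.areas.loc[fid]),
                ms2_ids=list(self.ms2_ids.get(fid, ())),
            )
            for fid in self.feature_ids
        ]
        return feats, samples

    # -- manipulation ------------------------------------------------------

    def with_areas(self, areas: pd.DataFrame) -> "FeatureTable":
        """Clone with a new area matrix (features and samples may be subsets)."""
        samples = self.samples.loc[list(areas.columns)]
        info = self.feature_info.loc[areas.index]
        return FeatureTable(areas, info, samples, self.ms2_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        return self.with_areas(self.areas.loc[list(feature_ids)])

    def with_ms2(self, ms2_ids: Mapping[str, Sequence[str]]) -> "FeatureTable":
        return FeatureTable(self.areas, self.feature_info, self.samples, ms2_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.areas.copy(), self.feature_info.copy(), self.samples.copy(), self.ms2_ids
        )

    def __len__(self) -> int:
        return self.n_features

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureTable({self.n_features} features x {self.n_samples} samples, "
            f"{len(self.blank_sample_ids())} blank)"
        )


def spectrum_from_arrays(
    spectrum_id: str,
    precursor_mz: float,
    mz: Sequence[float],
    intensity: Sequence[float],
    **kwargs,
) -> Spectrum:
    """Convenience constructor from parallel m/z / intensity sequences."""
    peaks = tuple(Peak(float(m), float(i)) for m, i in zip(mz, intensity))
    return Spectrum(id=spectrum_id, precursor_mz=precursor_mz, peaks=peaks, **kwargs)
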