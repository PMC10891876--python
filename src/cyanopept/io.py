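"""Readers and writers for the standard formats the pipeline touches.

MGF carries the MS/MS spectra (pyteomics does the block parsing), CSV the
feature matrix plus a sample-metadata sidecar, and GraphML the molecular
network (via networkx, ready for Cytoscape). The column conventions are
documented in ``docs/formats.md``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .model import FeatureTable, Peak, Spectrum

logger = logging.getLogger(__name__)


class MGFError(ValueError):
    """Raised for malformed MGF content, naming the offending block."""


def _parse_title(title: str | None, index: int) -> tuple[str, bool, str | None]:
    """Decode our TITLE convention: ``<id>|seed=<0|1>|sample=<sample_id>``."""
    if not title:
        return f"scan_{index}", False, None
    parts = [p.strip() for p in str(title).split("|")]
    spectrum_id = parts[0] or f"scan_{index}"
    is_seed = False
    sample_id: str | None = None
    for part in parts[1:]:
        if part.startswith("seed="):
            is_seed = part[5:] in ("1", "true", "True")
        elif part.startswith("sample="):
            sample_id = part[7:] or None
    return spectrum_id, is_seed, sample_id


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read centroided MS/MS spectra from an MGF file.

    Retention times are converted to minutes (RTINSECONDS / 60); spectra
    lacking a CHARGE line default to 1+ with a logged warning. Peaks come
    back sorted ascending in m/z.
    """
    spectra: list[Spectrum] = []
    defaulted_charge = 0
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            try:
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise MGFError(f"MGF block {index}: missing PEPMASS")
                precursor_mz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
                charge_field = params.get("charge")
                if charge_field:
                    charge = abs(int(charge_field[0]))
                else:
                    charge = 1
                    defaulted_charge += 1
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"]) / 60.0
                elif "rtinminutes" in params:
                    rt = float(params["rtinminutes"])
                else:
                    rt = 0.0
                mz = np.asarray(entry.get("m/z array", []), dtype=float)
                intensity = np.asarray(entry.get("intensity array", []), dtype=float)
                if (intensity < 0).any():
                    raise MGFError(f"MGF block {index}: negative intensity")
                spectrum_id, is_seed, sample_id = _parse_title(
                    params.get("title"), index
                )
                peaks = tuple(Peak(m, i) for m, i in zip(mz, intensity))
                spectra.append(
                    Spectrum(
                        id=spectrum_id,
                        precursor_mz=precursor_mz,
                        charge=charge,
                        rt=rt,
                        peaks=peaks,
                        sample_id=sample_id,
                        is_seed=is_seed,
                    )
                )
            except MGFError:
                raise
            except Exception as exc:  # malformed block content
                raise MGFError(f"MGF block {index}: {exc}") from exc
    if defaulted_charge:
        logger.info("read_mgf: %d spectra without CHARGE defaulted to 1+", defaulted_charge)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (m/z to 4 decimals, intensity to 1 decimal).

    The seed flag and sample id survive round-trips through the TITLE
    convention ``<id>|seed=<0|1>|sample=<sample_id>``.
    """
    if not spectra:
        raise ValueError("write_mgf: refusing to write an empty spectrum list")
    entries = []
    for s in spectra:
        if not s.peaks:
            raise ValueError(f"write_mgf: spectrum {s.id} has no peaks")
        title = f"{s.id}|seed={int(s.is_seed)}|sample={s.sample_id or ''}"
        entries.append(
            {
                "m/z array": np.round(s.mz_array, 4),
                "intensity array": np.round(s.intensity_array, 1),
                "params": {
                    "title": title,
                    "pepmass": round(s.precursor_mz, 4),
                    "charge": s.charge,
                    "rtinseconds": round(s.rt * 60.0, 3),
                },
            }
        )
    _mgf.write(
        entries,
        str(path),
        fragment_format="%.4f %.1f",
        write_charges=False,
        use_numpy=True,
        file_mode="w",
    )


def read_feature_table(
    matrix_path: str | Path, metadata_path: str | Path
) -> FeatureTable:
    """Read a feature matrix CSV plus its sample-metadata sidecar.

    The matrix CSV has columns ``feature_id, mz, rt, <sample_id...>``; the
    sidecar has ``sample_id, strain_label, replicate_index, is_blank,
    dry_biomass_mg`` (biomass empty for blanks). Missing matrix cells read
    as 0 with a logged count.
    """
    matrix = pd.read_csv(matrix_path, dtype={"feature_id": str})
    if matrix["feature_id"].duplicated().any():
        dupes = matrix.loc[matrix["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature ids in {matrix_path}: {dupes}")
    matrix = matrix.set_index("feature_id")
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str}).set_index("sample_id")
    meta["is_blank"] = meta["is_blank"].astype(bool)
    if "dry_biomass_mg" not in meta.columns:
        meta["dry_biomass_mg"] = np.nan
    sample_cols = [c for c in matrix.columns if c not in ("mz", "rt")]
    unknown = [c for c in sample_cols if c not in meta.index]
    if unknown:
        raise ValueError(
            f"samples present in matrix but absent from metadata: {unknown}"
        )
    areas = matrix[sample_cols]
    n_missing = int(areas.isna().sum().sum())
    if n_missing:
        logger.info("read_feature_table: %d missing cells read as 0", n_missing)
        areas = areas.fillna(0.0)
    return FeatureTable(areas, matrix[["mz", "rt"]], meta.loc[sample_cols])


def write_feature_table(
    table: FeatureTable, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a FeatureTable back to the matrix + metadata CSV pair."""
    out = pd.concat([table.feature_info.round({"mz": 4, "rt": 3}), table.areas], axis=1)
    out.index.name = "feature_id"
    out.to_csv(matrix_path)
    meta = table.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path)


def link_ms2_to_features(
    spectra: Iterable[Spectrum],
    table: FeatureTable,
    mz_tol_da: float = 0.01,
    rt_tol_min: float = 0.2,
) -> FeatureTable:
    """Associate DDA MS/MS spectra with MS1 features by precursor m/z and RT.

    A spectrum within tolerance of exactly one feature is linked to it;
    when several features qualify the nearest in m/z wins (logged). Peak
    areas are never modified, only the MS/MS links.
    """
    if mz_tol_da <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be positive")
    mz = table.feature_info["mz"].to_numpy()
    rt = table.feature_info["rt"].to_numpy()
    fids = np.asarray(table.feature_ids)
    links: dict[str, list[str]] = {fid: list(table.ms2_ids.get(fid, ())) for fid in fids}
    ambiguous = 0
    for s in spectra:
        mask = (np.abs(mz - s.precursor_mz) <= mz_tol_da) & (
            np.abs(rt - s.rt) <= rt_tol_min
        )
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            continue
        if hits.size > 1:
            ambiguous += 1
            hits = hits[np.argsort(np.abs(mz[hits] - s.precursor_mz), kind="stable")][:1]
        fid = str(fids[hits[0]])
        if s.id not in links[fid]:
            links[fid].append(s.id)
    if ambiguous:
        logger.info(
            "link_ms2_to_features: %d ambiguous spectra linked to nearest-m/z feature",
            ambiguous,
        )
    return table.with_ms2({fid: ids for fid, ids in links.items() if ids})


def write_graphml(network, path: str | Path) -> None:
    """Export a molecular network as GraphML for Cytoscape-style viewers.

    Node attributes: precursor m/z, RT, strain set, cyanopeptide group and
    provenance category (extract / seed / shared); edge attributes: cosine
    score and matched ion count. Set-valued attributes are flattened to
    comma-joined strings, as GraphML carries scalars only.
    """
    g = nx.Graph()
    source = network.graph if hasattr(network, "graph") else network
    for node, data in source.nodes(data=True):
        attrs = {}
        for key, value in data.items():
            if isinstance(value, (set, frozenset, tuple, list)):
                attrs[key] = ",".join(sorted(str(v) for v in value))
            elif value is None:
                attrs[key] = ""
            else:
                attrs[key] = value
        g.add_node(node, **attrs)
    for u, v, data in source.edges(data=True):
        g.add_edge(u, v, **{k: val for k, val in data.items() if val is not None})
    nx.write_graphml(g, str(path))
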