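"""Multivariate and nonparametric statistics on deconvoluted profiles.

PCA (with deterministic loading signs) visualises strain separation; a
Kruskal-Wallis test per feature with Benjamini-Hochberg correction flags
the features driving it (significant at adjusted p < 0.01); per-strain
Welch t-tests and log2 fold changes feed volcano-style label selection
(3 smallest p per strain plus the 3 largest loading arrows per PC1/PC2
quadrant); and biomass normalisation turns areas into area-per-mg for
relative-abundance summaries.

The Kruskal-Wallis test runs on imputed, unscaled areas: it is rank-based
and the log10/Pareto transform is monotone per feature, so the ranks (and
p-values) would be identical either way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .model import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class StatsConfig:
    alpha: float = 0.01
    label_top_t: int = 3  # features per strain (smallest t-test p)
    label_top_arrows: int = 3  # features per PC1/PC2 quadrant (largest arrows)
    pcs_shown: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.label_top_t < 0 or self.label_top_arrows < 0:
            raise ValueError("label counts must be >= 0")


@dataclass
class PcaResult:
    """Scores (samples x PCs), loadings (features x PCs), % variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def run_pca(scaled: pd.DataFrame) -> PcaResult:
    """Full PCA of a features x samples matrix of scaled values.

    Rows (features) are expected centred; the decomposition keeps every
    component so scores x loadings^T reconstructs the centred matrix.
    Sign convention: the largest-magnitude loading of each component is
    made positive, which fixes the otherwise arbitrary axis orientations.
    """
    if scaled.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    if scaled.shape[0] < 2:
        raise ValueError("PCA requires at least two features")
    x = scaled.to_numpy(dtype=float).T  # samples x features
    n_comp = min(x.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # features x components
    for k in range(n_comp):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=scaled.index, columns=cols),
        variance_pct=pca.explained_variance_ratio_ * 100.0,
    )


def _strain_groups(table: FeatureTable) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid in table.non_blank_sample_ids():
        groups.setdefault(table.strain_of(sid), []).append(sid)
    return groups


def kw_bh(
    table: FeatureTable, config: StatsConfig | None = None
) -> pd.DataFrame:
    """Kruskal-Wallis across strains per feature, BH-corrected.

    Returns a DataFrame indexed by feature id with columns ``statistic``,
    ``pvalue``, ``p_adj`` and ``significant`` (adjusted p < alpha).
    Constant features get statistic 0 and p 1 by convention.
    """
    config = config or StatsConfig()
    groups = _strain_groups(table)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two strains")
    for strain, sids in groups.items():
        if len(sids) < 2:
            raise ValueError(f"strain {strain} has fewer than two replicates")
    stats_out = np.zeros(table.n_features)
    pvals = np.ones(table.n_features)
    values = table.areas
    for k, fid in enumerate(values.index):
        per_group = [values.loc[fid, sids].to_numpy() for sids in groups.values()]
        pooled = np.concatenate(per_group)
        if np.allclose(pooled, pooled[0]):
            continue  # identical everywhere: H = 0, p = 1
        with warnings.catch_warnings():
            # ties-heavy imputed rows trip scipy's precision-loss warning
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = sps.kruskal(*per_group)
        stats_out[k] = stat
        pvals[k] = p
    reject, p_adj, _, _ = multipletests(pvals, alpha=config.alpha, method="fdr_bh")
    # flags follow the adjusted-p threshold, not multipletests' reject vector,
    # to keep the documented contract flag <=> p_adj < alpha (equivalent here)
    return pd.DataFrame(
        {
            "statistic": stats_out,
            "pvalue": pvals,
            "p_adj": p_adj,
            "significant": p_adj < config.alpha,
        },
        index=values.index,
    )


def volcano(table: FeatureTable) -> pd.DataFrame:
    """Per-strain one-vs-rest Welch t-tests and log2 fold changes.

    Tidy output with columns ``feature_id``, ``strain``, ``pvalue`` and
    ``log2_fc`` (log2 of the ratio of the strain's mean area to the mean
    over all other samples). Features with zero variance in both groups
    get p = 1 (logged).
    """
    groups = _strain_groups(table)
    if len(groups) < 2:
        raise ValueError("volcano contrasts require at least two strains")
    records = []
    degenerate = 0
    areas = table.areas
    for strain, sids in groups.items():
        rest = [s for s in table.non_blank_sample_ids() if s not in sids]
        a = areas[sids].to_numpy(dtype=float)
        b = areas[rest].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        p = np.where(flat, 1.0, p)
        degenerate += int(flat.sum())
        log2_fc = np.log2(a.mean(axis=1) / b.mean(axis=1))
        for fid, pv, fc in zip(areas.index, p, log2_fc):
            records.append(
                {"feature_id": fid, "strain": strain, "pvalue": float(pv),
                 "log2_fc": float(fc)}
            )
    if degenerate:
        logger.info("volcano: %d zero-variance contrasts set to p = 1", degenerate)
    return pd.DataFrame.from_records(records)


def select_loading_labels(
    pca: PcaResult,
    volcano_df: pd.DataFrame,
    config: StatsConfig | None = None,
) -> list[str]:
    """Features to label on the loading plot.

    Union of (a) per strain, the ``label_top_t`` features with smallest
    Welch p-value (ties broken by larger |log2 FC|, then feature id) and
    (b) per quadrant of the (PC1, PC2) loading plane, the
    ``label_top_arrows`` features with the largest loading-vector
    magnitude. Duplicates count once; the result is sorted.
    """
    config = config or StatsConfig()
    if pca.n_components < 2:
        raise ValueError("label selection needs at least two components")
    selected: set[str] = set()
    for strain, sub in volcano_df.groupby("strain"):
        ranked = sub.assign(abs_fc=sub["log2_fc"].abs()).sort_values(
            ["pvalue", "abs_fc", "feature_id"], ascending=[True, False, True]
        )
        selected.update(ranked["feature_id"].head(config.label_top_t))

    p1, p2 = (f"PC{k}" for k in config.pcs_shown)
    load = pca.loadings[[p1, p2]]
    magnitude = np.hypot(load[p1], load[p2])
    # quadrants by loading signs; exact zeros count as non-negative
    quadrant = pd.Series(
        [
            (load.at[f, p1] >= 0, load.at[f, p2] >= 0)
            for f in load.index
        ],
        index=load.index,
    )
    for _, members in magnitude.groupby(quadrant):
        top = members.sort_values(ascending=False, kind="stable")
        selected.update(top.head(config.label_top_arrows).index)
    return sorted(selected)


def normalize_biomass(table: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Peak areas per mg dry biomass, plus per-strain mean +/- sd summary.

    Every non-blank sample must carry a dry-biomass value; blanks are
    passed through unchanged (they have no biomass by definition).
    """
    biomass = table.samples["dry_biomass_mg"]
    missing = [
        sid for sid in table.non_blank_sample_ids() if pd.isna(biomass.loc[sid])
    ]
    if missing:
        raise ValueError(f"samples without dry biomass: {missing}")
    divisor = biomass.copy()
    divisor[table.samples["is_blank"].astype(bool)] = 1.0
    normalized = table.with_areas(table.areas.div(divisor, axis=1))

    rows = []
    for strain, sids in _strain_groups(table).items():
        sub = normalized.areas[sids]
        for fid in sub.index:
            rows.append(
                {
                    "feature_id": fid,
                    "strain": strain,
                    "mean_area_per_mg": float(sub.loc[fid].mean()),
                    "sd_area_per_mg": float(sub.loc[fid].std(ddof=1)),
                }
            )
    return normalized, pd.DataFrame.from_records(rows)
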