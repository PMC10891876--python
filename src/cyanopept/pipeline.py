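"""End-to-end orchestration and the distribution-table report.

``run_pipeline`` executes the full workflow on a synthetic scenario (or
on user-provided MGF + CSV inputs): deconvolution at the statistics
threshold (1e6) feeding PCA / Kruskal-Wallis / volcano labelling, a
parallel deconvolution at the networking threshold (1e5) feeding the
molecular network, spectrum classification (which ignores feature
thresholds - the rescue path), cyanopeptolin naming, and the per-strain x
per-group distribution table with its aggregation identities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (
    Classification,
    ClassifierConfig,
    CyanopeptolinNamer,
    classify_spectrum,
    name_cyanopeptolin,
)
from .deconvolution import (
    DeconvolutionConfig,
    deconvolute,
    impute_zeros,
    subtract_blank,
    transform_scale,
)
from .model import FeatureTable, Spectrum
from .network import (
    NetworkParams,
    SpectralNetwork,
    annotate_clusters,
    build_network,
    deconvolute_network,
    merge_consensus,
)
from .registry import CYANOPEPTIDE_GROUPS, DiagnosticRuleRegistry, default_registry
from .stats import StatsConfig, kw_bh, normalize_biomass, run_pca, select_loading_labels, volcano
from .synth import (
    GeneratorConfig,
    StrainSpec,
    default_seed_compounds,
    default_strain_specs,
    generate_library,
    make_seed_spectra,
    simulate_experiment,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distribution table


@dataclass
class DistributionTable:
    """Unique-cyanopeptide counts per group x strain with totals.

    ``counts[g, s]`` is the number of unique compounds of group g detected
    in strain s; ``group_totals[g]`` counts unique compounds per group
    across all strains (a union, not a sum, since compounds can be shared
    between strains). Identities:

    * strain_total(s) = sum over groups of counts[g, s]
    * grand_total = sum of group_totals
    * max_s counts[g, s] <= group_total(g) <= sum_s counts[g, s]
    """

    counts: pd.DataFrame  # groups x strains
    group_totals: pd.Series

    @property
    def strain_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.group_totals.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["group_total"] = self.group_totals
        out.loc["strain_total"] = out.sum(axis=0)
        out.loc["strain_total", "group_total"] = self.grand_total
        return out.astype(int)


def check_table_consistency(table: DistributionTable) -> list[str]:
    """Violated aggregation identities (empty when consistent)."""
    violations: list[str] = []
    for strain in table.counts.columns:
        expected = int(table.counts[strain].sum())
        if int(table.strain_totals[strain]) != expected:
            violations.append(f"strain_total({strain}) != column sum")
    if table.grand_total != int(table.group_totals.sum()):
        violations.append("grand_total != sum of group totals")
    for group in table.counts.index:
        row = table.counts.loc[group]
        total = int(table.group_totals[group])
        if not int(row.max() if len(row) else 0) <= total <= int(row.sum()):
            violations.append(
                f"group_total({group})={total} outside [max over strains, sum over strains]"
            )
    return violations


def build_distribution_table(
    classified: pd.DataFrame, table: FeatureTable, rt_cluster_tol: float = 0.05
) -> DistributionTable:
    """Tabulate unique cyanopeptides per group and strain.

    ``classified`` needs columns ``feature_id, group, subclass,
    neutral_mass, rt`` (unclassified rows are ignored). Unique-compound
    identity is (group, subclass, integer neutral mass, RT cluster within
    ``rt_cluster_tol`` min) - the identity notion behind the systematic
    naming convention. A compound counts for a strain when any of its
    features has area > 0 in at least one replicate of that strain.
    """
    strains = table.strain_labels()
    groups = [g for g in CYANOPEPTIDE_GROUPS]
    counts = pd.DataFrame(0, index=groups, columns=strains, dtype=int)
    totals = pd.Series(0, index=groups, dtype=int)

    usable = classified[classified["group"].isin(groups)].copy()
    if usable.empty:
        return DistributionTable(counts, totals)

    strain_samples = {
        strain: [s for s in table.non_blank_sample_ids() if table.strain_of(s) == strain]
        for strain in strains
    }

    def detected_strains(fid: str) -> set[str]:
        if fid not in table.areas.index:
            return set()
        row = table.areas.loc[fid]
        return {
            strain for strain, sids in strain_samples.items() if (row[sids] > 0).any()
        }

    usable["int_mass"] = usable["neutral_mass"].map(math.floor)
    usable["subclass_key"] = usable["subclass"].fillna("")
    usable = usable.sort_values(["group", "subclass_key", "int_mass", "rt"])
    compound_strains: list[tuple[str, set[str]]] = []
    last_key = None
    last_rt = None
    for _, row in usable.iterrows():
        key = (row["group"], row["subclass_key"], row["int_mass"])
        if key != last_key or (last_rt is not None and row["rt"] - last_rt > rt_cluster_tol):
            compound_strains.append((row["group"], set()))
            last_key = key
        last_rt = row["rt"]
        compound_strains[-1][1].update(detected_strains(row["feature_id"]))

    for group, strain_set in compound_strains:
        totals[group] += 1
        for strain in strain_set:
            counts.loc[group, strain] += 1
    return DistributionTable(counts, totals)


def load_reference_distribution() -> DistributionTable:
    """The published distribution of detected cyanopeptides across the six
    Planktothrix CPCC strains, shipped as package data (used for identity
    checks and as the default-scenario template)."""
    ref = resources.files("cyanopept.data").joinpath("reference_strain_counts.csv")
    with ref.open("r", encoding="utf-8") as handle:
        df = pd.read_csv(handle).set_index("group")
    return DistributionTable(
        counts=df.drop(columns="group_total").astype(int),
        group_totals=df["group_total"].astype(int),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Nested configuration of every pipeline stage."""

    seed: int = 0
    outdir: str | Path = "pipeline_out"
    strain_specs: Sequence[StrainSpec] | None = None  # None -> default scenario
    generator: GeneratorConfig | None = None
    deconv_stats: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    deconv_network: DeconvolutionConfig = field(
        default_factory=DeconvolutionConfig.networking_profile
    )
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    make_plots: bool = True
    n_seed_shared: int = 4
    n_seed_only: int = 3


@dataclass
class PipelineResult:
    outdir: Path
    table_stats: FeatureTable
    scaled: pd.DataFrame
    pca: object
    significance: pd.DataFrame
    labels: list[str]
    classifications: pd.DataFrame
    network: SpectralNetwork
    distribution: DistributionTable
    ground_truth: object | None = None


def _classify_spectra(
    spectra: Sequence[Spectrum],
    registry: DiagnosticRuleRegistry,
    config: ClassifierConfig,
) -> list[Classification]:
    return [classify_spectrum(s, registry, config) for s in spectra if s.peaks]


def classifications_per_feature(
    spectra: Sequence[Spectrum],
    classifications: Sequence[Classification],
    table: FeatureTable,
) -> pd.DataFrame:
    """Aggregate spectrum classifications to features.

    Each feature takes the classification of its linked spectra (they
    agree on clean data; the most frequent group wins otherwise).
    Returns columns feature_id, group, subclass, chlorinated, neutral_mass, rt.
    """
    by_id = {c.spectrum_id: c for c in classifications}
    spec_by_id = {s.id: s for s in spectra}
    rows = []
    for fid in table.feature_ids:
        linked = [by_id[sid] for sid in table.ms2_ids.get(fid, ()) if sid in by_id]
        if not linked:
            continue
        votes: dict[tuple[str, str | None], int] = {}
        for c in linked:
            votes[(c.group, c.subclass)] = votes.get((c.group, c.subclass), 0) + 1
        (group, subclass), _ = max(votes.items(), key=lambda kv: (kv[1], kv[0][0]))
        spectrum = spec_by_id[linked[0].spectrum_id]
        rows.append(
            {
                "feature_id": fid,
                "group": group,
                "subclass": subclass,
                "chlorinated": any(c.chlorine_count > 0 for c in linked),
                "neutral_mass": spectrum.neutral_mass,
                "rt": float(table.feature_info.loc[fid, "rt"]),
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["feature_id", "group", "subclass", "chlorinated",
                       "neutral_mass", "rt"]
    )


def name_cyanopeptolins(classified: pd.DataFrame) -> pd.Series:
    """Systematic names for classified cyanopeptolins, assigned in elution
    order per (subclass, integer mass); indexed by feature id."""
    namer = CyanopeptolinNamer()
    cps = classified[
        (classified["group"] == "cyanopeptolin") & classified["subclass"].notna()
    ].sort_values("rt", kind="stable")
    names = {}
    for _, row in cps.iterrows():
        c = Classification(
            spectrum_id=row["feature_id"], group="cyanopeptolin",
            subclass=row["subclass"],
        )
        names[row["feature_id"]] = name_cyanopeptolin(
            c, row["neutral_mass"], row["rt"], namer
        )
    return pd.Series(names, dtype=object)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full synthetic-scenario workflow and write all outputs."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    gen = config.generator or GeneratorConfig(seed=config.seed)
    strain_specs = (
        list(config.strain_specs) if config.strain_specs else default_strain_specs()
    )

    log_path = outdir / "run_log.jsonl"
    log_handle = log_path.open("w", encoding="utf-8")

    def log_event(stage: str, **payload) -> None:
        record = {"stage": stage, **payload}
        log_handle.write(json.dumps(record, sort_keys=True, default=str) + "\n")

    def stage(name: str):
        log_event(name, status="start")
        return name

    try:
        # ---- generate -----------------------------------------------------
        stage("generate")
        table, spectra, truth = simulate_experiment(strain_specs, gen, registry)
        rng = np.random.default_rng(gen.seed + 1)
        library = generate_library(strain_specs, gen, np.random.default_rng(gen.seed),
                                   registry)
        seed_compounds = default_seed_compounds(
            library, rng, config.n_seed_shared, config.n_seed_only
        )
        seed_spectra = make_seed_spectra(seed_compounds, gen, rng, registry)
        log_event("generate", status="done", n_features=table.n_features,
                  n_spectra=len(spectra), n_seed_spectra=len(seed_spectra))
        cio.write_feature_table(
            table, outdir / "features_raw.csv", outdir / "samples.csv"
        )
        cio.write_mgf(spectra + seed_spectra, outdir / "spectra.mgf")
        truth.to_csv(outdir / "ground_truth.csv")

        # ---- classification (threshold-independent rescue path) -----------
        stage("classify")
        log_event("classify", tol_ppm=config.classifier.tol_ppm,
                  intense_fraction=config.classifier.intense_fraction)
        classifications = _classify_spectra(spectra, registry, config.classifier)
        classified = classifications_per_feature(spectra, classifications, table)
        names = name_cyanopeptolins(classified)
        classified["name"] = classified["feature_id"].map(names)
        classified.to_csv(outdir / "classifications.tsv", sep="\t", index=False)
        log_event("classify", status="done",
                  n_classified=int((classified["group"] != "unclassified").sum()))

        # ---- branch A: statistics at 1e6 ----------------------------------
        stage("deconvolute_stats")
        audit: list = []
        log_event("deconvolute_stats",
                  intensity_threshold=config.deconv_stats.intensity_threshold,
                  mz_range=config.deconv_stats.mz_range,
                  rt_range=config.deconv_stats.rt_range,
                  blank_multiplier=config.deconv_stats.blank_multiplier)
        table_deconv = deconvolute(table, config.deconv_stats, audit)
        table_stats = impute_zeros(table_deconv, config.deconv_stats)
        pd.DataFrame(audit, columns=["feature_id", "rule", "detail"]).to_csv(
            outdir / "deconvolution_audit.tsv", sep="\t", index=False
        )
        cio.write_feature_table(
            table_stats, outdir / "features_stats.csv", outdir / "samples_stats.csv"
        )
        scaled = transform_scale(table_stats)
        scaled.to_csv(outdir / "scaled_matrix.csv")

        stage("statistics")
        pca = run_pca(scaled)
        pca.scores.to_csv(outdir / "pca_scores.csv")
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        significance = kw_bh(table_stats, config.stats)
        significance.to_csv(outdir / "significance.tsv", sep="\t")
        volcano_df = volcano(table_stats)
        volcano_df.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        labels = select_loading_labels(pca, volcano_df, config.stats)
        (outdir / "loading_labels.txt").write_text("\n".join(labels) + "\n")
        normalized, abundance = normalize_biomass(table_stats)
        abundance.to_csv(outdir / "relative_abundance.tsv", sep="\t", index=False)
        log_event("statistics", status="done",
                  pc1_pct=float(pca.variance_pct[0]),
                  pc2_pct=float(pca.variance_pct[1]),
                  n_significant=int(significance["significant"].sum()),
                  n_labels=len(labels), alpha=config.stats.alpha)

        # ---- branch B: networking at 1e5 ----------------------------------
        stage("network")
        log_event("network",
                  intensity_threshold=config.deconv_network.intensity_threshold,
                  **{k: getattr(config.network, k) for k in
                     ("precursor_tol", "fragment_tol", "min_cosine", "topk",
                      "max_component", "min_matched_ions", "min_cluster_size",
                      "min_base_peak_intensity")})
        table_net = deconvolute(table, config.deconv_network)
        surviving = set(table_net.feature_ids)
        kept_ids = {
            sid for fid in surviving for sid in table.ms2_ids.get(fid, ())
        }
        net_spectra = [s for s in spectra if s.id in kept_ids] + seed_spectra
        consensus = merge_consensus(net_spectra, config.network)
        network = build_network(consensus, config.network)

        node_groups: dict[str, str] = {}
        identified: set[str] = set()
        blank_nodes: set[str] = set()
        class_by_feature = classified.set_index("feature_id")
        for cid, cons in network.consensus.items():
            cls = classify_spectrum(cons.spectrum, registry, config.classifier)
            node_groups[cid] = cls.group
            if cls.is_cyanopeptide and cons.provenance != "seed":
                identified.add(cid)
            feature_hits = cons.feature_ids & set(table.feature_ids)
            if feature_hits and all(
                truth.role_of(f) == "blank" for f in feature_hits
            ):
                blank_nodes.add(cid)
        network = deconvolute_network(
            network,
            mz_range=config.deconv_network.mz_range,
            rt_range=config.deconv_network.rt_range,
            blank_node_ids=blank_nodes,
            identified_ids=identified,
        )
        network = annotate_clusters(network, node_groups)
        cio.write_graphml(network, outdir / "network.graphml")
        log_event("network", status="done", n_nodes=network.n_nodes,
                  n_edges=network.n_edges,
                  n_components=len(network.components()))

        # ---- distribution table -------------------------------------------
        stage("report")
        # detection uses blank-subtracted, *unfiltered* areas: compounds below
        # the statistics threshold still count as detected (the fragmentation
        # rescue path), but blank-derived signal never does; imputed values
        # must not count, so the imputed table is unsuitable here
        table_detect = subtract_blank(table, config.deconv_stats)
        distribution = build_distribution_table(classified, table_detect)
        distribution.to_frame().to_csv(outdir / "distribution_table.tsv", sep="\t")
        violations = check_table_consistency(distribution)
        if violations:
            raise RuntimeError(f"distribution table inconsistent: {violations}")
        log_event("report", status="done", grand_total=distribution.grand_total)

        if config.make_plots:
            stage("plots")
            _write_plots(outdir, table_stats, pca, significance, labels, abundance)
            log_event("plots", status="done")
    except Exception as exc:
        log_event("error", error=str(exc))
        log_handle.close()
        raise
    log_handle.close()

    return PipelineResult(
        outdir=outdir,
        table_stats=table_stats,
        scaled=scaled,
        pca=pca,
        significance=significance,
        labels=labels,
        classifications=classified,
        network=network,
        distribution=distribution,
        ground_truth=truth,
    )


def _write_plots(outdir, table, pca, significance, labels, abundance) -> None:
    """PCA scores, loading arrows and relative-abundance plots as SVG."""
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 5))
    strains = table.samples.loc[pca.scores.index, "strain_label"]
    for strain in sorted(strains.unique()):
        mask = strains == strain
        ax.scatter(pca.scores.loc[mask, "PC1"], pca.scores.loc[mask, "PC2"],
                   label=strain, s=30)
    ax.set_xlabel(f"PC1 ({pca.variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.variance_pct[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(plots / "pca_scores.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    sig = significance["significant"]
    for fid in pca.loadings.index:
        colour = "red" if sig.get(fid, False) else "black"
        ax.annotate(
            "", xy=(pca.loadings.at[fid, "PC1"], pca.loadings.at[fid, "PC2"]),
            xytext=(0, 0), arrowprops=dict(arrowstyle="->", color=colour, lw=0.6),
        )
        if fid in labels:
            ax.text(pca.loadings.at[fid, "PC1"], pca.loadings.at[fid, "PC2"], fid,
                    fontsize=5)
    lim = float(np.abs(pca.loadings[["PC1", "PC2"]].to_numpy()).max()) * 1.1
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("PC1 loading")
    ax.set_ylabel("PC2 loading")
    fig.tight_layout()
    fig.savefig(plots / "pca_loadings.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    pivot = abundance.pivot_table(
        index="strain", values="mean_area_per_mg", aggfunc="sum"
    )
    ax.bar(pivot.index, pivot["mean_area_per_mg"])
    ax.set_ylabel("summed mean area per mg")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(plots / "relative_abundance.svg")
    plt.close(fig)
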