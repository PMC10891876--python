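"""GNPS-style molecular networking with the modified cosine score.

The modified cosine matches fragment peaks either directly or shifted by
the precursor mass difference, takes a one-to-one peak matching by greedy
selection on descending square-root-intensity products (the GNPS-era
convention), and normalises so identical spectra score 1. Networks keep
an edge only when the score and the matched-ion count clear their
thresholds, mutual TopK pruning thins hairballs, and oversized connected
components are repaired by deleting their weakest edges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import Peak, Spectrum

__all__ = [
    "NetworkParams",
    "ConsensusSpectrum",
    "SpectralNetwork",
    "modified_cosine",
    "merge_consensus",
    "build_network",
    "deconvolute_network",
    "annotate_clusters",
]


@dataclass
class NetworkParams:
    """Networking parameters (defaults follow the workflow this models)."""

    precursor_tol: float = 0.02  # Th
    fragment_tol: float = 0.03  # Th
    min_cosine: float = 0.7
    topk: int = 10
    max_component: int = 100
    min_matched_ions: int = 7
    min_cluster_size: int = 2
    min_base_peak_intensity: float = 5e6
    keep_singletons: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_cosine <= 1:
            raise ValueError("min_cosine must be in (0, 1]")
        for name in ("precursor_tol", "fragment_tol", "topk", "max_component",
                     "min_matched_ions", "min_cluster_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def modified_cosine(
    a: Spectrum, b: Spectrum, params: NetworkParams | None = None
) -> tuple[float, int]:
    """Modified cosine similarity and matched ion count of two spectra.

    Peaks match directly (|dm/z| <= fragment_tol) or shifted by the
    precursor m/z difference; among all candidate pairs a one-to-one
    matching is chosen greedily on descending sqrt-intensity products.
    The score is symmetric, lies in [0, 1], and reduces to the plain
    cosine when the precursor masses agree.
    """
    params = params or NetworkParams()
    if not a.peaks or not b.peaks:
        raise ValueError("modified_cosine requires non-empty spectra")
    amz, ai = a.mz_array, np.sqrt(a.intensity_array)
    bmz, bi = b.mz_array, np.sqrt(b.intensity_array)
    norm = math.sqrt(float(np.sum(ai**2)) * float(np.sum(bi**2)))
    if norm == 0:
        return 0.0, 0

    shift = a.precursor_mz - b.precursor_mz
    shifts = [0.0]
    if abs(shift) > params.fragment_tol:
        shifts.append(shift)

    candidates: list[tuple[float, int, int]] = []
    for s in shifts:
        # a_mz ~= b_mz + s
        j0 = np.searchsorted(bmz, amz - s - params.fragment_tol)
        j1 = np.searchsorted(bmz, amz - s + params.fragment_tol, side="right")
        for i in range(amz.size):
            for j in range(j0[i], j1[i]):
                candidates.append((float(ai[i] * bi[j]), i, j))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    matched = 0
    for product, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += product
        matched += 1
    return min(1.0, total / norm), matched


@dataclass
class ConsensusSpectrum:
    """A merged (consensus) spectrum entering the network.

    provenance is "extract", "seed" or "shared" depending on whether the
    members came from strain extracts, seed references, or both.
    """

    id: str
    spectrum: Spectrum
    member_ids: tuple[str, ...]
    provenance: str
    strain_labels: frozenset[str] = frozenset()

    @property
    def precursor_mz(self) -> float:
        return self.spectrum.precursor_mz

    @property
    def rt(self) -> float:
        return self.spectrum.rt

    @property
    def feature_ids(self) -> frozenset[str]:
        """Feature ids recoverable from member spectrum ids (id convention
        ``<feature>__s<k>``); empty-string-free."""
        out = set()
        for mid in self.member_ids:
            base = mid.split("__")[0]
            if base:
                out.add(base)
        return frozenset(out)


def _merge_peaks(members: Sequence[Spectrum], fragment_tol: float) -> tuple[Peak, ...]:
    """Align member peaks within tolerance and average their intensities."""
    pooled = sorted((p.mz, p.intensity) for s in members for p in s.peaks)
    merged: list[Peak] = []
    group_mz: list[float] = []
    group_int: list[float] = []
    for mz, intensity in pooled:
        if group_mz and mz - group_mz[0] > fragment_tol:
            merged.append(
                Peak(float(np.mean(group_mz)), float(sum(group_int)) / len(members))
            )
            group_mz, group_int = [], []
        group_mz.append(mz)
        group_int.append(intensity)
    if group_mz:
        merged.append(Peak(float(np.mean(group_mz)), float(sum(group_int)) / len(members)))
    return tuple(merged)


def merge_consensus(
    spectra: Sequence[Spectrum],
    params: NetworkParams | None = None,
    sample_strains: Mapping[str, str] | None = None,
    keep_singletons: bool | None = None,
) -> list[ConsensusSpectrum]:
    """Greedy precursor-window + cosine clustering into consensus spectra.

    Spectra whose precursors agree within ``precursor_tol`` and whose
    modified cosine against the cluster representative reaches
    ``min_cosine`` are merged (peak-wise mean of aligned peaks); groups
    smaller than ``min_cluster_size`` are dropped unless singletons are
    kept. Provenance is the union of member provenances.
    """
    params = params or NetworkParams()
    if keep_singletons is None:
        keep_singletons = params.keep_singletons
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.id))
    reps: list[Spectrum] = []
    clusters: list[list[Spectrum]] = []
    for s in ordered:
        best = None
        best_cos = params.min_cosine
        for k in range(len(reps) - 1, -1, -1):
            rep = reps[k]
            if s.precursor_mz - rep.precursor_mz > params.precursor_tol:
                break
            cos, _ = modified_cosine(s, rep, params)
            if cos >= best_cos:
                best, best_cos = k, cos
        if best is None:
            reps.append(s)
            clusters.append([s])
        else:
            clusters[best].append(s)

    out: list[ConsensusSpectrum] = []
    idx = 0
    for members in clusters:
        if len(members) < params.min_cluster_size and not keep_singletons:
            continue
        seeds = sum(m.is_seed for m in members)
        provenance = (
            "seed" if seeds == len(members) else "extract" if seeds == 0 else "shared"
        )
        strains = frozenset(
            (sample_strains or {}).get(m.sample_id, m.sample_id.rsplit("_r", 1)[0])
            for m in members
            if not m.is_seed and m.sample_id
        )
        cid = f"n{idx:04d}"
        idx += 1
        consensus = Spectrum(
            id=cid,
            precursor_mz=float(np.mean([m.precursor_mz for m in members])),
            charge=members[0].charge,
            rt=float(np.mean([m.rt for m in members])),
            peaks=_merge_peaks(members, params.fragment_tol),
            is_seed=provenance == "seed",
        )
        out.append(
            ConsensusSpectrum(
                id=cid,
                spectrum=consensus,
                member_ids=tuple(sorted(m.id for m in members)),
                provenance=provenance,
                strain_labels=strains,
            )
        )
    return out


@dataclass
class SpectralNetwork:
    """The molecular network: a networkx graph plus its parameters.

    Node attributes: precursor_mz, rt, provenance, strains, cluster.
    Edge attributes: cosine, matched_ions.
    """

    graph: nx.Graph
    params: NetworkParams
    consensus: dict[str, ConsensusSpectrum] = field(default_factory=dict)

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def assign_cluster_ids(self) -> None:
        """Deterministic cluster ids: components by descending size then id."""
        comps = sorted(
            nx.connected_components(self.graph), key=lambda c: (-len(c), min(c))
        )
        for k, comp in enumerate(comps, start=1):
            for node in comp:
                self.graph.nodes[node]["cluster"] = k


def build_network(
    consensus: Sequence[ConsensusSpectrum], params: NetworkParams | None = None
) -> SpectralNetwork:
    """Score all pairs and assemble the pruned molecular network.

    Edges require cosine >= min_cosine and >= min_matched_ions matched
    peaks; mutual TopK pruning keeps an edge only when each endpoint
    ranks the other within its top K by cosine; components above
    ``max_component`` are split by iteratively deleting their
    lowest-cosine edges.
    """
    params = params or NetworkParams()
    nodes = [
        c for c in consensus
        if c.spectrum.base_peak_intensity >= params.min_base_peak_intensity
    ]
    graph = nx.Graph()
    for c in nodes:
        graph.add_node(
            c.id,
            precursor_mz=round(c.precursor_mz, 4),
            rt=round(c.rt, 3),
            provenance=c.provenance,
            strains=c.strain_labels,
        )
    scored: list[tuple[str, str, float, int]] = []
    for a, b in itertools.combinations(nodes, 2):
        cos, matched = modified_cosine(a.spectrum, b.spectrum, params)
        if cos >= params.min_cosine and matched >= params.min_matched_ions:
            scored.append((a.id, b.id, cos, matched))

    # mutual TopK: each endpoint must rank the other within its top K
    ranks: dict[str, list[tuple[float, str]]] = {}
    for u, v, cos, _ in scored:
        ranks.setdefault(u, []).append((-cos, v))
        ranks.setdefault(v, []).append((-cos, u))
    topk_of = {
        node: {vid for _, vid in sorted(pairs)[: params.topk]}
        for node, pairs in ranks.items()
    }
    for u, v, cos, matched in scored:
        if v in topk_of.get(u, ()) and u in topk_of.get(v, ()):
            graph.add_edge(u, v, cosine=round(cos, 6), matched_ions=matched)

    _enforce_component_size(graph, params.max_component)
    net = SpectralNetwork(graph, params, {c.id: c for c in nodes})
    net.assign_cluster_ids()
    return net


def _enforce_component_size(graph: nx.Graph, max_component: int) -> None:
    """Iteratively cut the weakest edge of any oversized component."""
    while True:
        oversized = [
            c for c in nx.connected_components(graph) if len(c) > max_component
        ]
        if not oversized:
            return
        comp = oversized[0]
        weakest = min(
            (e for e in graph.edges(comp, data=True) if e[0] in comp and e[1] in comp),
            key=lambda e: (e[2]["cosine"], min(e[0], e[1]), max(e[0], e[1])),
        )
        graph.remove_edge(weakest[0], weakest[1])


def deconvolute_network(
    network: SpectralNetwork,
    mz_range: tuple[float, float] = (590.0, 1210.0),
    rt_range: tuple[float, float] = (2.2, 5.6),
    blank_node_ids: Iterable[str] = (),
    identified_ids: Iterable[str] = (),
) -> SpectralNetwork:
    """Post-network cleanup: drop blank-derived and out-of-window nodes,
    and singleton nodes unless identified as a cyanopeptide."""
    blank = set(blank_node_ids)
    identified = set(identified_ids)
    graph = network.graph.copy()
    drop = set()
    for node, data in graph.nodes(data=True):
        if node in blank:
            drop.add(node)
        elif not mz_range[0] <= data["precursor_mz"] <= mz_range[1]:
            drop.add(node)
        elif not rt_range[0] <= data["rt"] <= rt_range[1]:
            drop.add(node)
    graph.remove_nodes_from(drop)
    singles = [
        node for node in graph.nodes
        if graph.degree(node) == 0 and node not in identified
    ]
    graph.remove_nodes_from(singles)
    net = SpectralNetwork(
        graph, network.params,
        {k: v for k, v in network.consensus.items() if k in graph},
    )
    net.assign_cluster_ids()
    return net


def annotate_clusters(
    network: SpectralNetwork, classifications: Mapping[str, str]
) -> SpectralNetwork:
    """Label each component with the majority classifier group of its nodes.

    ``classifications`` maps node id -> group name ("unclassified" nodes
    and nodes without an entry do not vote). Components without a strict
    majority among voting nodes are labelled "mixed"; components with no
    votes at all get "unannotated".
    """
    for comp in network.components():
        votes: dict[str, int] = {}
        for node in comp:
            group = classifications.get(node)
            if group and group != "unclassified":
                votes[group] = votes.get(group, 0) + 1
        if not votes:
            label = "unannotated"
        else:
            ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                label = "mixed"
            else:
                label = ranked[0][0]
        for node in comp:
            network.graph.nodes[node]["group"] = label
    return network
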