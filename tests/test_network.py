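"""Modified cosine, consensus merging, network construction and annotation."""

import itertools

import numpy as np
import pytest

from cyanopept.model import Peak, Spectrum, spectrum_from_arrays
from cyanopept.network import (
    ConsensusSpectrum,
    NetworkParams,
    annotate_clusters,
    build_network,
    deconvolute_network,
    merge_consensus,
    modified_cosine,
)
from cyanopept.synth import CompoundSpec, GeneratorConfig, render_spectrum


# -- oracles ----------------------------------------------------------------


def brute_force_cosine(a, b, params):
    """Exhaustive maximum over all one-to-one candidate matchings."""
    ai = np.sqrt(a.intensity_array)
    bi = np.sqrt(b.intensity_array)
    amz, bmz = a.mz_array, b.mz_array
    norm = np.sqrt((ai**2).sum() * (bi**2).sum())
    shift = a.precursor_mz - b.precursor_mz
    shifts = [0.0] + ([shift] if abs(shift) > params.fragment_tol else [])
    cands = [
        (float(ai[i] * bi[j]), i, j)
        for s in shifts
        for i in range(amz.size)
        for j in range(bmz.size)
        if abs(amz[i] - s - bmz[j]) <= params.fragment_tol
    ]
    best = [0.0, 0]

    def recurse(k, used_a, used_b, total, n):
        if (total, n) > tuple(best):
            best[0], best[1] = total, n
        for m in range(k, len(cands)):
            p, i, j = cands[m]
            if i not in used_a and j not in used_b:
                recurse(m + 1, used_a | {i}, used_b | {j}, total + p, n + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return min(1.0, best[0] / norm), best[1]


def random_spectrum(rng, sid, precursor, n_peaks):
    return spectrum_from_arrays(
        sid, precursor, np.sort(rng.uniform(100, 600, n_peaks)),
        rng.uniform(1, 100, n_peaks),
    )


# -- modified cosine --------------------------------------------------------


def test_self_similarity_is_one(net_params):
    s = spectrum_from_arrays("s", 700.0, [100.0, 200.0, 300.0], [10.0, 20.0, 30.0])
    score, matched = modified_cosine(s, s, net_params)
    assert score == pytest.approx(1.0)
    assert matched == 3


def test_disjoint_spectra_score_zero(net_params):
    a = spectrum_from_arrays("a", 700.0, [100.0, 200.0], [10.0, 10.0])
    b = spectrum_from_arrays("b", 700.0, [150.0, 250.0], [10.0, 10.0])
    assert modified_cosine(a, b, net_params) == (0.0, 0)


def test_empty_spectrum_is_an_error(net_params):
    a = spectrum_from_arrays("a", 700.0, [100.0], [1.0])
    with pytest.raises(ValueError):
        modified_cosine(a, Spectrum("e", 700.0), net_params)


def test_toy_direct_plus_shifted_match_equals_exhaustive_oracle(net_params):
    # one direct match (150.0) and one precursor-shifted match (300 vs 310)
    a = spectrum_from_arrays("a", 710.0, [150.0, 310.0, 400.0], [50.0, 80.0, 20.0])
    b = spectrum_from_arrays("b", 700.0, [150.0, 300.0, 520.0], [40.0, 90.0, 10.0])
    assert modified_cosine(a, b, net_params) == pytest.approx(
        brute_force_cosine(a, b, net_params)
    )


def test_greedy_matching_agrees_with_oracle_on_random_small_spectra(net_params):
    rng = np.random.default_rng(42)
    for _ in range(40):
        a = random_spectrum(rng, "a", float(rng.uniform(600, 900)),
                            int(rng.integers(3, 11)))
        b = random_spectrum(rng, "b", a.precursor_mz + float(rng.uniform(-50, 50)),
                            int(rng.integers(3, 11)))
        got = modified_cosine(a, b, net_params)
        want = brute_force_cosine(a, b, net_params)
        assert got[0] == pytest.approx(want[0])
        assert got[1] == want[1]


def test_symmetry_and_bounds(net_params):
    rng = np.random.default_rng(8)
    for _ in range(30):
        a = random_spectrum(rng, "a", float(rng.uniform(600, 900)),
                            int(rng.integers(2, 15)))
        b = random_spectrum(rng, "b", float(rng.uniform(600, 900)),
                            int(rng.integers(2, 15)))
        sab = modified_cosine(a, b, net_params)
        sba = modified_cosine(b, a, net_params)
        assert sab[0] == pytest.approx(sba[0])
        assert sab[1] == sba[1]
        assert 0.0 <= sab[0] <= 1.0


def test_equal_precursors_reduce_to_plain_cosine(net_params):
    a = spectrum_from_arrays("a", 700.0, [100.0, 200.0, 300.0], [4.0, 9.0, 16.0])
    b = spectrum_from_arrays("b", 700.0, [100.0, 200.0, 350.0], [16.0, 9.0, 4.0])
    # plain cosine on sqrt intensities: (2*4 + 3*3) / (sqrt(29) * sqrt(29))
    expected = (2 * 4 + 3 * 3) / 29.0
    score, matched = modified_cosine(a, b, net_params)
    assert score == pytest.approx(expected)
    assert matched == 2


def test_agrees_with_matchms_reference_implementation(net_params):
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(12)
    ref = ModifiedCosine(tolerance=net_params.fragment_tol)
    for _ in range(15):
        a = random_spectrum(rng, "a", float(rng.uniform(600, 900)),
                            int(rng.integers(4, 12)))
        b = random_spectrum(rng, "b", a.precursor_mz + float(rng.uniform(-30, 30)),
                            int(rng.integers(4, 12)))
        ma = matchms.Spectrum(
            mz=a.mz_array, intensities=np.sqrt(a.intensity_array),
            metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False,
        )
        mb = matchms.Spectrum(
            mz=b.mz_array, intensities=np.sqrt(b.intensity_array),
            metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False,
        )
        res = ref.pair(ma, mb)
        got, n = modified_cosine(a, b, net_params)
        assert got == pytest.approx(float(res["score"]), abs=1e-6)
        assert n == int(res["matches"])


# -- consensus merging ------------------------------------------------------


def _renders(compound, n, rng, config):
    return [
        render_spectrum(compound, config, rng, spectrum_id=f"{compound.compound_id}__s{k}",
                        sample_id=f"strainA_r{k+1}")
        for k in range(n)
    ]


def test_near_identical_spectra_merge_into_one_consensus(net_params):
    rng = np.random.default_rng(3)
    config = GeneratorConfig(seed=3, ppm_sigma=0.0, noise_peaks_per_spectrum=2)
    c = CompoundSpec("c1", "microcystin", None, 900.0, 1, 3.0,
                     backbone_mzs=tuple(np.linspace(250, 500, 10)))
    merged = merge_consensus(_renders(c, 2, rng, config), net_params)
    assert len(merged) == 1
    assert merged[0].provenance == "extract"


def test_lone_spectrum_is_dropped_at_min_cluster_size_two(net_params):
    rng = np.random.default_rng(3)
    config = GeneratorConfig(seed=3, ppm_sigma=0.0)
    c = CompoundSpec("c1", "microcystin", None, 900.0, 1, 3.0)
    spectra = _renders(c, 1, rng, config)
    assert merge_consensus(spectra, net_params) == []
    kept = merge_consensus(spectra, net_params, keep_singletons=True)
    assert len(kept) == 1


def test_spectra_of_three_compounds_give_three_consensus_nodes(net_params):
    rng = np.random.default_rng(6)
    config = GeneratorConfig(seed=6, ppm_sigma=0.0, noise_peaks_per_spectrum=2)
    compounds = [
        CompoundSpec(f"c{k}", "microcystin", None, 800.0 + 40 * k, 1, 3.0,
                     backbone_mzs=tuple(np.sort(rng.uniform(250, 500, 10))))
        for k in range(3)
    ]
    spectra = []
    for k, c in enumerate(compounds):
        spectra.extend(_renders(c, (4, 3, 3)[k], rng, config))
    merged = merge_consensus(spectra, net_params)
    assert len(merged) == 3
    # ground-truth partition: members of each node come from one compound
    for node in merged:
        assert len(node.feature_ids) == 1


def test_seed_and_extract_members_mark_the_consensus_shared(net_params):
    rng = np.random.default_rng(9)
    config = GeneratorConfig(seed=9, ppm_sigma=0.0, noise_peaks_per_spectrum=0)
    c = CompoundSpec("c1", "anabaenopeptin", "exo-Arg", 850.0, 1, 3.0,
                     backbone_mzs=tuple(np.linspace(250, 500, 8)))
    extract = _renders(c, 2, rng, config)
    seed = render_spectrum(c, config, rng, spectrum_id="c1__seed",
                           sample_id="seed", is_seed=True)
    merged = merge_consensus(extract + [seed], net_params)
    assert len(merged) == 1
    assert merged[0].provenance == "shared"


# -- network construction ---------------------------------------------------


def _block_spectrum(sid, precursor, blocks, rng, weight=1.0):
    mzs = np.sort(np.concatenate(blocks))
    intensities = rng.uniform(40, 100, mzs.size) * weight
    return ConsensusSpectrum(
        id=sid,
        spectrum=spectrum_from_arrays(sid, precursor, mzs, intensities * 1e6, rt=3.0),
        member_ids=(sid,),
        provenance="extract",
    )


def test_three_mutually_similar_spectra_form_one_component(net_params):
    rng = np.random.default_rng(1)
    shared = rng.uniform(200, 500, 10)
    nodes = [
        _block_spectrum(f"n{k}", 700.0 + k * 0.5, [shared], rng) for k in range(3)
    ]
    net = build_network(nodes, net_params)
    assert len(net.components()) == 1
    assert net.n_edges == 3


def test_every_retained_edge_satisfies_both_thresholds(net_params):
    rng = np.random.default_rng(2)
    blocks = [rng.uniform(150 + 40 * k, 180 + 40 * k, 8) for k in range(8)]
    nodes = []
    for k in range(12):
        picks = [blocks[k % 8], blocks[(k + 1) % 8]]
        nodes.append(_block_spectrum(f"n{k:02d}", 650.0 + 3 * k, picks, rng))
    net = build_network(nodes, net_params)
    for _, _, data in net.graph.edges(data=True):
        assert data["cosine"] >= net_params.min_cosine
        assert data["matched_ions"] >= net_params.min_matched_ions


def test_mutual_topk_one_keeps_only_mutual_best_edges():
    rng = np.random.default_rng(5)
    params = NetworkParams(topk=1, min_cosine=0.1, min_matched_ions=7)
    hub_blocks = [rng.uniform(150 + 30 * k, 170 + 30 * k, 7) for k in range(14)]
    nodes = [_block_spectrum("hub", 700.0, hub_blocks, rng)]
    for k in range(14):
        own = rng.uniform(620, 640, 3)
        nodes.append(_block_spectrum(f"leaf{k:02d}", 702.0 + k, [hub_blocks[k], own], rng))
    net = build_network(nodes, params)

    # oracle: an edge survives iff each endpoint ranks the other first
    scored = {}
    for a, b in itertools.combinations(nodes, 2):
        cos, matched = modified_cosine(a.spectrum, b.spectrum, params)
        if cos >= params.min_cosine and matched >= params.min_matched_ions:
            scored[(a.id, b.id)] = cos
    neighbors = {}
    for (u, v), cos in scored.items():
        neighbors.setdefault(u, []).append((cos, v))
        neighbors.setdefault(v, []).append((cos, u))
    top1 = {n: max(edges)[1] for n, edges in neighbors.items()}
    expected = {
        tuple(sorted((u, v)))
        for (u, v) in scored
        if top1.get(u) == v and top1.get(v) == u
    }
    got = {tuple(sorted(e)) for e in net.graph.edges}
    assert got == expected
    assert all(net.graph.degree(n) <= 1 for n in net.graph.nodes)


def test_oversized_chain_is_cut_into_components_below_the_cap():
    rng = np.random.default_rng(7)
    params = NetworkParams(max_component=10, min_matched_ions=7, topk=10)
    blocks = [rng.uniform(150 + 12 * k, 160 + 12 * k, 8) for k in range(31)]
    nodes = [
        _block_spectrum(f"n{k:02d}", 650.0 + 2 * k, [blocks[k], blocks[k + 1]], rng)
        for k in range(30)
    ]
    net = build_network(nodes, params)
    sizes = [len(c) for c in net.components()]
    assert max(sizes) <= 10
    assert sum(sizes) == 30  # nodes survive, only edges are cut


def test_small_network_equals_brute_force_reference(net_params):
    """On <=10 spectra the built network equals an explicit all-pairs +
    mutual-TopK + component-cut reference."""
    rng = np.random.default_rng(11)
    blocks = [rng.uniform(150 + 35 * k, 185 + 35 * k, 9) for k in range(6)]
    nodes = []
    for k in range(9):
        picks = [blocks[k % 6], blocks[(k + 2) % 6]]
        nodes.append(_block_spectrum(f"n{k}", 640.0 + 4 * k, picks, rng))
    params = NetworkParams(topk=3, max_component=4, min_cosine=0.5, min_matched_ions=7)
    net = build_network(nodes, params)

    # reference
    import networkx as nx

    scored = {}
    for a, b in itertools.combinations(nodes, 2):
        cos, matched = modified_cosine(a.spectrum, b.spectrum, params)
        if cos >= params.min_cosine and matched >= params.min_matched_ions:
            scored[(a.id, b.id)] = cos
    neighbors = {}
    for (u, v), cos in scored.items():
        neighbors.setdefault(u, []).append((-cos, v))
        neighbors.setdefault(v, []).append((-cos, u))
    topk = {n: {v for _, v in sorted(edges)[: params.topk]}
            for n, edges in neighbors.items()}
    ref = nx.Graph()
    ref.add_nodes_from(n.id for n in nodes)
    for (u, v), cos in scored.items():
        if v in topk[u] and u in topk[v]:
            ref.add_edge(u, v, cosine=round(cos, 6))
    while True:
        oversized = [c for c in nx.connected_components(ref) if len(c) > params.max_component]
        if not oversized:
            break
        comp = oversized[0]
        weakest = min(
            ((u, v, d) for u, v, d in ref.edges(comp, data=True)
             if u in comp and v in comp),
            key=lambda e: (e[2]["cosine"], min(e[0], e[1]), max(e[0], e[1])),
        )
        ref.remove_edge(weakest[0], weakest[1])

    assert set(net.graph.edges) == set(ref.edges)
    assert max(len(c) for c in net.components()) <= params.max_component


# -- post-network deconvolution and annotation ------------------------------


def _singleton(sid, precursor, provenance="extract"):
    rng = np.random.default_rng(sum(map(ord, sid)))
    node = _block_spectrum(sid, precursor, [rng.uniform(200, 500, 10)], rng)
    node.provenance = provenance
    return node


def test_network_deconvolution_rules(net_params):
    nodes = [
        _singleton("decoy", 800.0),
        _singleton("identified_ag", 820.0),
        _singleton("heavy", 1300.0),
    ]
    net = build_network(nodes, net_params)  # all singletons, no edges
    cleaned = deconvolute_network(
        net, blank_node_ids=[], identified_ids=["identified_ag"]
    )
    assert set(cleaned.graph.nodes) == {"identified_ag"}


def test_blank_nodes_are_removed_even_when_connected(net_params):
    rng = np.random.default_rng(21)
    shared = rng.uniform(200, 500, 10)
    nodes = [_block_spectrum(f"n{k}", 700.0 + k, [shared], rng) for k in range(3)]
    net = build_network(nodes, net_params)
    cleaned = deconvolute_network(net, blank_node_ids=["n1"], identified_ids=["n0", "n2"])
    assert "n1" not in cleaned.graph.nodes


def test_cluster_annotation_majority_tie_and_provenance(net_params):
    rng = np.random.default_rng(13)
    shared = rng.uniform(200, 500, 12)
    nodes = []
    for k in range(5):
        node = _block_spectrum(f"m{k}", 700.0 + 0.5 * k, [shared], rng)
        if k == 4:
            node.provenance = "shared"
        nodes.append(node)
    shared2 = rng.uniform(200, 500, 12)
    nodes += [_block_spectrum(f"t{k}", 900.0 + 0.5 * k, [shared2], rng) for k in range(4)]
    net = build_network(nodes, net_params)
    groups = {f"m{k}": "microcystin" for k in range(5)}
    groups.update({"t0": "cyanopeptolin", "t1": "cyanopeptolin",
                   "t2": "anabaenopeptin", "t3": "anabaenopeptin"})
    net = annotate_clusters(net, groups)
    labels = {n: d["group"] for n, d in net.graph.nodes(data=True)}
    assert labels["m0"] == "microcystin"
    assert labels["t0"] == "mixed"
    assert net.graph.nodes["m4"]["provenance"] == "shared"
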