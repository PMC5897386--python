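"""Alpha-weighted global alignment of two co-occurrence networks.

Each candidate node pair (u in network 1, v in network 2, same node kind) is
scored ``alpha * seqsim(u, v) + (1 - alpha) * toposim(u, v)`` where seqsim is
16S sequence identity (name identity for abiotic variables) and toposim is
graphlet-degree-vector similarity.  Alpha follows the convention where 1
means sequence-only and 0 topology-only alignment.

The optimizer is a deterministic greedy seed-and-extend: a priority queue of
candidate pairs keyed by node score plus ``edge_bonus`` times the number of
already-aligned neighbour pairs the candidate would conserve; the best pair
(ties broken by lexicographic id pair) is committed, neighbour extensions are
re-queued, and the process stops when no candidate reaches ``min_score`` or
the smaller network is exhausted.  Alignment quality is summarised by edge
correctness (EC, conserved fraction of the smaller network's edges) and the
symmetric substructure score (SS, conserved edges over the union of source
edges and edges induced on the image).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    OTU_KIND,
    VARIABLE_KIND,
    AlignmentResult,
    CooccurrenceNetwork,
    SeqSimilarityMatrix,
    ValidationError,
)
from .graphlets import graphlet_degree_vectors, signature_similarity_matrix
from .inference import randomize_network


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def pairwise_identity(
    seqs: dict[str, str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SeqSimilarityMatrix:
    """Global pairwise identities: matches / alignment length under a global
    alignment with the given scores."""
    from Bio import Align

    if len(seqs) < 2:
        raise ValidationError("need at least 2 sequences")
    for name, seq in seqs.items():
        if not seq:
            raise ValidationError(f"empty sequence {name!r}")
        if set(seq) - set("ACGTN"):
            raise ValidationError(f"non-nucleotide characters in {name!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    names = list(seqs)
    n = len(names)
    ident = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        aln = aligner.align(seqs[names[i]], seqs[names[j]])[0]
        a, b = str(aln[0]), str(aln[1])
        matches = sum(1 for ca, cb in zip(a, b) if ca == cb and ca != "-")
        ident[i, j] = ident[j, i] = matches / len(a)
    return SeqSimilarityMatrix(identity=pd.DataFrame(ident, index=names, columns=names))


# ---------------------------------------------------------------------------
# Node scoring
# ---------------------------------------------------------------------------

def node_score(u, v, alpha: float, seqsim: float, toposim: float) -> float:
    """Mixing score ``alpha * seqsim + (1 - alpha) * toposim``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    for s in (seqsim, toposim):
        if not 0.0 <= s <= 1.0 + 1e-12:
            raise ValidationError("similarities must be in [0, 1]")
    return alpha * seqsim + (1.0 - alpha) * toposim


def _sequence_similarity_matrix(
    nodes1: list[str],
    nodes2: list[str],
    kinds1: dict,
    kinds2: dict,
    seqsim: SeqSimilarityMatrix | None,
) -> np.ndarray:
    """Cross-network sequence similarity; variable nodes use name identity,
    and cross-kind pairs are ineligible (similarity -inf)."""
    sim = np.full((len(nodes1), len(nodes2)), -np.inf)
    ids = seqsim.identity if seqsim is not None else None
    for i, u in enumerate(nodes1):
        for j, v in enumerate(nodes2):
            if kinds1[u] != kinds2[v]:
                continue
            if kinds1[u] == VARIABLE_KIND:
                sim[i, j] = 1.0 if u == v else 0.0
            elif ids is None:
                sim[i, j] = 1.0 if u == v else 0.0
            else:
                try:
                    sim[i, j] = float(ids.at[u, v])
                except KeyError as exc:
                    raise ValidationError(
                        f"sequence similarity missing for pair ({u}, {v})"
                    ) from exc
    return sim


# ---------------------------------------------------------------------------
# Greedy seed-and-extend alignment
# ---------------------------------------------------------------------------

def align(
    net1: CooccurrenceNetwork,
    net2: CooccurrenceNetwork,
    alpha: float = 0.6,
    seqsim: SeqSimilarityMatrix | None = None,
    edge_bonus: float = 0.5,
    min_score: float = 0.0,
    max_graphlet: int = 4,
) -> AlignmentResult:
    """Align two networks; deterministic for identical inputs.

    When ``seqsim`` is omitted, OTU sequence similarity degenerates to id
    identity (1 for the same id, else 0) — useful for self-alignment and
    synthetic data where ids are shared.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if net1.n_nodes == 0 or net2.n_nodes == 0:
        raise ValidationError("cannot align an empty network")
    nodes1 = sorted(net1.graph.nodes())
    nodes2 = sorted(net2.graph.nodes())
    kinds1 = {n: net1.graph.nodes[n].get("kind", OTU_KIND) for n in nodes1}
    kinds2 = {n: net2.graph.nodes[n].get("kind", OTU_KIND) for n in nodes2}
    idx1 = {n: i for i, n in enumerate(nodes1)}
    idx2 = {n: i for i, n in enumerate(nodes2)}

    gdv1 = graphlet_degree_vectors(net1, max_graphlet)
    gdv2 = graphlet_degree_vectors(net2, max_graphlet)
    topo = signature_similarity_matrix(
        np.array([gdv1[n] for n in nodes1]),
        np.array([gdv2[n] for n in nodes2]),
    )
    seq = _sequence_similarity_matrix(nodes1, nodes2, kinds1, kinds2, seqsim)
    eligible = np.isfinite(seq)
    mixed = alpha * np.where(eligible, seq, 0.0) + (1.0 - alpha) * topo
    base = np.where(eligible, mixed, -np.inf)

    adj1 = {n: set(net1.graph.neighbors(n)) for n in nodes1}
    adj2 = {n: set(net2.graph.neighbors(n)) for n in nodes2}

    bonus = {}
    heap: list[tuple] = []
    for i, u in enumerate(nodes1):
        for j, v in enumerate(nodes2):
            if np.isfinite(base[i, j]) and base[i, j] >= min_score:
                heapq.heappush(heap, (-base[i, j], u, v, 0))

    mapping: dict[str, str] = {}
    node_scores: dict[str, float] = {}
    used2: set[str] = set()
    limit = min(len(nodes1), len(nodes2))
    while heap and len(mapping) < limit:
        negs, u, v, b = heapq.heappop(heap)
        if u in mapping or v in used2:
            continue
        current_b = bonus.get((u, v), 0)
        if b != current_b:  # stale entry; re-queue with the current bonus
            score = base[idx1[u], idx2[v]] + edge_bonus * current_b
            heapq.heappush(heap, (-score, u, v, current_b))
            continue
        score = -negs
        if score < min_score:
            break
        mapping[u] = v
        node_scores[u] = float(base[idx1[u], idx2[v]])
        used2.add(v)
        for un in adj1[u]:
            if un in mapping:
                continue
            for vn in adj2[v]:
                if vn in used2 or kinds1[un] != kinds2[vn]:
                    continue
                if not np.isfinite(base[idx1[un], idx2[vn]]):
                    continue
                nb = bonus.get((un, vn), 0) + 1
                bonus[(un, vn)] = nb
                new_score = base[idx1[un], idx2[vn]] + edge_bonus * nb
                if new_score >= min_score:
                    heapq.heappush(heap, (-new_score, un, vn, nb))

    ec, ss, conserved = alignment_scores_from_mapping(mapping, net1, net2)
    return AlignmentResult(
        alpha=alpha,
        mapping=mapping,
        node_scores=node_scores,
        ec=ec,
        ss=ss,
        conserved_edges=conserved,
    )


# ---------------------------------------------------------------------------
# EC / SS scoring
# ---------------------------------------------------------------------------

def alignment_scores_from_mapping(
    mapping: dict[str, str],
    net1: CooccurrenceNetwork,
    net2: CooccurrenceNetwork,
) -> tuple[float | None, float | None, list[tuple[str, str]]]:
    """EC and SS (percent) of an injective mapping net1 -> net2.

    Scoring is oriented so the network with fewer edges is the source: with f
    the mapping and C the conserved edge count, ``EC = 100 C / |E_source|``
    and ``SS = 100 C / (|E_source| + |E_target induced on image| - C)``.
    An empty source edge set leaves both scores undefined (None).
    """
    if net1.n_edges <= net2.n_edges:
        fwd = mapping
        src, dst = net1, net2
    else:
        fwd = {v: u for u, v in mapping.items()}
        src, dst = net2, net1
    e_src = src.n_edges
    if e_src == 0:
        return None, None, []
    conserved = []
    c = 0
    for u, w in src.graph.edges():
        fu, fw = fwd.get(u), fwd.get(w)
        if fu is not None and fw is not None and dst.graph.has_edge(fu, fw):
            c += 1
            conserved.append((u, w) if src is net1 else (fu, fw))
    image = set(fwd.values())
    induced = sum(1 for a, b in dst.graph.edges() if a in image and b in image)
    ec = 100.0 * c / e_src
    denom = e_src + induced - c
    ss = 100.0 * c / denom if denom > 0 else 0.0
    return ec, ss, sorted(conserved)


def alignment_scores(
    result: AlignmentResult, net1: CooccurrenceNetwork, net2: CooccurrenceNetwork
) -> tuple[float | None, float | None]:
    ec, ss, _ = alignment_scores_from_mapping(result.mapping, net1, net2)
    return ec, ss


# ---------------------------------------------------------------------------
# Alpha scan
# ---------------------------------------------------------------------------

def alpha_scan(
    net1: CooccurrenceNetwork,
    net2: CooccurrenceNetwork,
    seqsim: SeqSimilarityMatrix | None = None,
    grid=None,
    edge_bonus: float = 0.5,
    max_graphlet: int = 4,
) -> tuple[pd.DataFrame, float, dict[float, AlignmentResult]]:
    """Align at every alpha on the grid (default 0, 0.1, ..., 1.0).

    Returns the score table, the consensus alpha (the grid point maximising
    the harmonic mean of EC and SS; ties broken towards smaller alpha) and
    the per-alpha results.
    """
    if grid is None:
        grid = [round(0.1 * k, 1) for k in range(11)]
    rows = []
    results = {}
    best_alpha, best_h = None, -1.0
    for alpha in grid:
        res = align(
            net1, net2, alpha=alpha, seqsim=seqsim,
            edge_bonus=edge_bonus, max_graphlet=max_graphlet,
        )
        results[alpha] = res
        ec = res.ec if res.ec is not None else float("nan")
        ss = res.ss if res.ss is not None else float("nan")
        h = 2 * ec * ss / (ec + ss) if ec + ss > 0 else 0.0
        rows.append(
            {
                "alpha": alpha,
                "EC": ec,
                "SS": ss,
                "harmonic_mean": h,
                "n_aligned": res.n_aligned,
                "n_aligned_to_self": res.n_aligned_to_self,
            }
        )
        if np.isfinite(h) and h > best_h + 1e-12:
            best_h, best_alpha = h, alpha
    table = pd.DataFrame(rows)
    return table, best_alpha, results


# ---------------------------------------------------------------------------
# Validation against randomized networks
# ---------------------------------------------------------------------------

def compare_to_random(
    net1: CooccurrenceNetwork,
    net2: CooccurrenceNetwork,
    n_random: int = 20,
    alpha: float = 0.6,
    seqsim: SeqSimilarityMatrix | None = None,
    seed: int = 0,
    edge_bonus: float = 0.5,
    max_graphlet: int = 4,
) -> dict:
    """EC/SS of the real pair versus alignments against edge-shuffled
    versions of net2; z = (real - mean_random) / sd_random."""
    if n_random <= 0:
        raise ValidationError("n_random must be positive")
    real = align(net1, net2, alpha=alpha, seqsim=seqsim,
                 edge_bonus=edge_bonus, max_graphlet=max_graphlet)
    ecs, sss = [], []
    for k in range(n_random):
        rnd = randomize_network(net2, seed=seed + k)
        res = align(net1, rnd, alpha=alpha, seqsim=seqsim,
                    edge_bonus=edge_bonus, max_graphlet=max_graphlet)
        ecs.append(res.ec if res.ec is not None else 0.0)
        sss.append(res.ss if res.ss is not None else 0.0)

    def z(real_val, vals):
        if real_val is None:
            return float("nan")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if sd == 0:
            return float("inf") if real_val > np.mean(vals) else float("-inf")
        return float((real_val - np.mean(vals)) / sd)

    return {
        "ec_real": real.ec,
        "ss_real": real.ss,
        "ec_random_mean": float(np.mean(ecs)),
        "ec_random_sd": float(np.std(ecs, ddof=1)) if n_random > 1 else 0.0,
        "ss_random_mean": float(np.mean(sss)),
        "ss_random_sd": float(np.std(sss, ddof=1)) if n_random > 1 else 0.0,
        "z_ec": z(real.ec, ecs),
        "z_ss": z(real.ss, sss),
    }


# ---------------------------------------------------------------------------
# Hiveplot export
# ---------------------------------------------------------------------------

def hiveplot_export(
    result: AlignmentResult,
    net1: CooccurrenceNetwork,
    net2: CooccurrenceNetwork,
    core: set[str],
    rel_abundance: dict[str, float] | None = None,
) -> dict:
    """Data model for a hiveplot view of an alignment: per node its axis
    (network), sub-axis (core/noncore), rank by log relative abundance and
    size by degree centrality; alignment pairs become the central edges."""
    def axis_nodes(net, axis):
        n = net.graph.number_of_nodes()
        out = []
        for node in net.otu_nodes:
            ra = (rel_abundance or {}).get(node, 0.0)
            out.append(
                {
                    "id": node,
                    "axis": axis,
                    "sub_axis": "core" if node in core else "noncore",
                    "log_abundance": float(np.log10(ra)) if ra > 0 else None,
                    "degree_centrality": net.graph.degree(node) / max(n - 1, 1),
                }
            )
        for rank, rec in enumerate(
            sorted(out, key=lambda r: (r["log_abundance"] is None, r["log_abundance"]))
        ):
            rec["rank"] = rank
        return out

    return {
        "axes": {
            "network1": axis_nodes(net1, "network1"),
            "network2": axis_nodes(net2, "network2"),
        },
        "alignment_edges": [
            {"from": u, "to": v, "score": result.node_scores.get(u)}
            for u, v in sorted(result.mapping.items())
        ],
        "alpha": result.alpha,
        "EC": result.ec,
        "SS": result.ss,
    }
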