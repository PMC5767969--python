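"""Dereplication, identity clustering, and sequence similarity networks.

Pairwise significance is an internal Smith-Waterman (BLOSUM62, affine gaps
11/1) converted to an E-value with Karlin-Altschul statistics using the
pinned gapped-BLOSUM62 parameters; E-values are carried in log10 space so
the 1e-100 edge threshold is stable far below floating-point underflow.
Identity clustering follows the greedy longest-first incremental scheme
(cd-hit style, without the word-filter heuristics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

# pinned Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_LOG10_EVALUE_THRESHOLD = -100.0

SCORING_METADATA = {
    "matrix": "BLOSUM62",
    "gap_open": GAP_OPEN,
    "gap_extend": GAP_EXTEND,
    "ka_lambda": KA_LAMBDA,
    "ka_k": KA_K,
}


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class DedupResult:
    representatives: list[tuple[str, str]]  # (id, sequence)
    members: dict[str, list[str]]  # representative id -> duplicate ids


def dedup_exact(sequences: list[tuple[str, str]]) -> DedupResult:
    """Collapse exact string duplicates; first-seen id is representative."""
    reps: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    by_seq: dict[str, str] = {}
    for sid, seq in sequences:
        if seq in by_seq:
            members[by_seq[seq]].append(sid)
        else:
            by_seq[seq] = sid
            reps.append((sid, seq))
            members[sid] = []
    return DedupResult(representatives=reps, members=members)


def global_identity(a: str, b: str) -> float:
    """Matches / alignment length of a global alignment."""
    aligner = _global_aligner()
    alignment = next(iter(aligner.align(a, b)))
    s1, s2 = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def cluster_at_identity(
    sequences: list[tuple[str, str]], threshold: float
) -> list[list[str]]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are sorted by length descending (ties by id for
    determinism); each sequence joins the first existing representative
    with identity >= threshold, otherwise founds a new cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(sequences, key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str]] = []
    clusters: dict[str, list[str]] = {}
    for sid, seq in ordered:
        placed = False
        for rid, rseq in reps:
            if seq == rseq or global_identity(seq, rseq) >= threshold:
                clusters[rid].append(sid)
                placed = True
                break
        if not placed:
            reps.append((sid, seq))
            clusters[sid] = [sid]
    return [clusters[rid] for rid, _ in reps]


def pairwise_log10_evalue(a: str, b: str, db_size: int) -> float:
    """log10 E-value of the local alignment of a vs b.

    E = K * m * n_db * exp(-lambda * S) with m = query length and the
    database search space ``db_size`` total residues; evaluated in both
    query/subject orders and the minimum returned, so the measure is
    symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _local_aligner()
    score = aligner.score(a, b)  # SW score is symmetric in its arguments
    # evaluating both query/subject orders and taking the minimum reduces
    # to using the shorter sequence as the query
    m = min(len(a), len(b))
    return math.log10(KA_K * m * max(db_size, 1)) - KA_LAMBDA * score / math.log(10)


def pairwise_evalue(a: str, b: str, db_size: int) -> float:
    """E-value as a float (0.0 when below the representable minimum)."""
    log10_e = pairwise_log10_evalue(a, b, db_size)
    return 10.0**log10_e if log10_e > -300 else 0.0


@dataclass
class SimilarityNetwork:
    graph: nx.Graph
    log10_threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def components(self) -> list[list[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        return comps


def build_network(
    sequences: list[tuple[str, str]],
    log10_threshold: float = DEFAULT_LOG10_EVALUE_THRESHOLD,
    node_attrs: dict[str, dict] | None = None,
) -> SimilarityNetwork:
    """All-vs-all similarity network at a log10 E-value edge threshold.

    ``sequences`` should already be deduplicated. Node attributes
    (subfamily, substrates, genus, ...) may be attached via ``node_attrs``.
    """
    graph = nx.Graph()
    node_attrs = node_attrs or {}
    db_size = sum(len(s) for _, s in sequences)
    for sid, seq in sequences:
        graph.add_node(sid, length=len(seq), **node_attrs.get(sid, {}))
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            (id_a, seq_a), (id_b, seq_b) = sequences[i], sequences[j]
            log10_e = pairwise_log10_evalue(seq_a, seq_b, db_size)
            if log10_e <= log10_threshold:
                graph.add_edge(id_a, id_b, log10_evalue=log10_e)
    return SimilarityNetwork(
        graph=graph,
        log10_threshold=log10_threshold,
        metadata=dict(SCORING_METADATA, db_size=db_size),
    )


@dataclass
class ClusterFamily:
    component_id: int
    members: list[str]
    name: str


def name_families(
    network: SimilarityNetwork,
    architectures: dict[str, list[str]] | None = None,
    genera: dict[str, str] | None = None,
) -> list[ClusterFamily]:
    """Name each connected component from its conserved cluster
    architecture and majority producing genus.

    ``architectures`` maps node id -> sorted domain names of its gene
    cluster (the CDPS itself is implicit); ``genera`` maps node id ->
    genus. Name format: ``CDPS[+dom...]|genus|c<i>``; unmapped components
    are named by index alone.
    """
    architectures = architectures or {}
    genera = genera or {}
    families = []
    for idx, comp in enumerate(network.components):
        doms: set[str] = set()
        mapped = False
        for node in comp:
            if node in architectures:
                doms.update(architectures[node])
                mapped = True
        genus_counts: dict[str, int] = {}
        for node in comp:
            g = genera.get(node)
            if g:
                genus_counts[g] = genus_counts.get(g, 0) + 1
        if mapped or genus_counts:
            arch = "+".join(["CDPS"] + sorted(doms))
            genus = (
                sorted(genus_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                if genus_counts
                else "unknown"
            )
            name = f"{arch}|{genus}|c{idx}"
        else:
            name = f"c{idx}"
        families.append(ClusterFamily(component_id=idx, members=comp, name=name))
    return families


def export_edge_list(network: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlog10_evalue\n")
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['log10_evalue']:.3f}\n")


def export_node_table(network: SimilarityNetwork, path: str | Path) -> None:
    keys = sorted({k for _, d in network.graph.nodes(data=True) for k in d})
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(keys) + "\n")
        for node, data in sorted(network.graph.nodes(data=True)):
            fh.write(node + "\t" + "\t".join(str(data.get(k, "")) for k in keys) + "\n")


def export_graphml(network: SimilarityNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))
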