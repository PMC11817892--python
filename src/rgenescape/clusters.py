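"""R-gene cluster detection and cross-assembly comparison.

R genes in plant genomes occur in tandem clusters of recently duplicated
paralogs.  A cluster here is a genomic region of at most 1.0 Mb holding
at least three homologous R proteins; homology is an all-vs-all local
alignment edge (identity >= 40%, bidirectional coverage >= 50%), and
cluster members must share a connected component of the homology graph.
Clusters from two assemblies are compared through an ortholog map to
flag assembly-specific clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .classify import RCategory, RGene


@dataclass
class RGeneCluster:
    cluster_id: str
    chrom_id: str
    span: tuple[int, int]
    members: list[str]  # >= 3 R gene ids, ordered by position
    category_mode: Optional[RCategory]

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError(f"cluster {self.cluster_id}: needs >= 3 members")
        if self.span[1] - self.span[0] > 1_000_000:
            raise ValueError(f"cluster {self.cluster_id}: span exceeds 1.0 Mb")


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def pairwise_identity_coverage(
    a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> tuple[float, float, float]:
    """Best local alignment of two proteins.

    Returns (percent identity over aligned columns, coverage of a,
    coverage of b); coverage is the aligned span over sequence length.
    """
    aligner = aligner or _aligner()
    try:
        alignment = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0, 0.0
    matches = 0
    cols = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        cols += e1 - s1
        matches += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    if cols == 0:
        return 0.0, 0.0, 0.0
    cov_a = (alignment.aligned[0][-1][1] - alignment.aligned[0][0][0]) / len(a)
    cov_b = (alignment.aligned[1][-1][1] - alignment.aligned[1][0][0]) / len(b)
    return 100.0 * matches / cols, cov_a, cov_b


def homology_graph(
    proteins: dict[str, str],
    id_min: float = 40.0,
    cov_min: float = 0.50,
) -> nx.Graph:
    """All-vs-all homology edges among R proteins.

    An undirected edge joins two genes when local-alignment identity is
    >= ``id_min`` percent with coverage >= ``cov_min`` of both sequences.
    Genes with missing protein sequences must be excluded by the caller.
    """
    g = nx.Graph()
    ids = sorted(proteins)
    g.add_nodes_from(ids)
    aligner = _aligner()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident, cov_a, cov_b = pairwise_identity_coverage(
                proteins[a], proteins[b], aligner
            )
            if ident >= id_min and cov_a >= cov_min and cov_b >= cov_min:
                g.add_edge(a, b, identity=ident, coverage=min(cov_a, cov_b))
    return g


def detect_clusters(
    r_genes: Sequence[RGene],
    graph: nx.Graph,
    window: int = 1_000_000,
    min_members: int = 3,
) -> list[RGeneCluster]:
    """Greedy left-to-right cluster calling within homology components.

    Per chromosome and per connected component, maximal runs of member
    genes whose span (first start to last end) fits in ``window`` are
    emitted when they hold >= ``min_members`` genes.  Clusters from
    different components may interleave but never share members.
    """
    by_id = {rg.gene.gene_id: rg for rg in r_genes}
    clusters: list[RGeneCluster] = []
    n = 0
    for component in nx.connected_components(graph):
        members = sorted(
            (by_id[gid] for gid in component if gid in by_id),
            key=lambda rg: (rg.gene.chrom_id, rg.gene.start),
        )
        by_chrom: dict[str, list[RGene]] = {}
        for rg in members:
            by_chrom.setdefault(rg.gene.chrom_id, []).append(rg)
        for chrom, genes in sorted(by_chrom.items()):
            i = 0
            while i < len(genes):
                j = i
                while (
                    j + 1 < len(genes)
                    and genes[j + 1].gene.end - genes[i].gene.start <= window
                ):
                    j += 1
                if j - i + 1 >= min_members:
                    run = genes[i : j + 1]
                    n += 1
                    cats = Counter(rg.category for rg in run)
                    clusters.append(
                        RGeneCluster(
                            cluster_id=f"cluster{n}",
                            chrom_id=chrom,
                            span=(run[0].gene.start, run[-1].gene.end),
                            members=[rg.gene.gene_id for rg in run],
                            category_mode=cats.most_common(1)[0][0],
                        )
                    )
                    i = j + 1
                else:
                    i += 1
    clusters.sort(key=lambda c: (c.chrom_id, c.span[0]))
    return clusters


def project_clusters(
    clusters_a: Sequence[RGeneCluster],
    clusters_b: Sequence[RGeneCluster],
    ortholog_map: dict[str, str],
    known_a: Optional[set[str]] = None,
    known_b: Optional[set[str]] = None,
    overlap_min: float = 0.5,
) -> dict[str, str]:
    """Label each A cluster "shared" or "A-specific" via orthology into B.

    A cluster is shared when at least ``overlap_min`` of its members
    have orthologs inside some cluster of the other assembly.  When the
    gene universes (``known_a``/``known_b``) are given, map entries
    referencing unknown genes are fatal.
    """
    if known_a is not None or known_b is not None:
        bad = [
            f"{a}->{b}"
            for a, b in ortholog_map.items()
            if (known_a is not None and a not in known_a)
            or (known_b is not None and b not in known_b)
        ]
        if bad:
            raise ValueError(f"ortholog map references unknown genes: {sorted(bad)}")
    b_clustered = {gid for c in clusters_b for gid in c.members}
    labels = {}
    for c in clusters_a:
        hits = sum(
            1 for gid in c.members if ortholog_map.get(gid) in b_clustered
        )
        labels[c.cluster_id] = (
            "shared" if hits / len(c.members) >= overlap_min else "A-specific"
        )
    return labels


def specificity_counts(
    labels: dict[str, str], clusters_a: Sequence[RGeneCluster]
) -> dict[str, Counter]:
    """Per-category tallies of shared vs specific clusters."""
    out: dict[str, Counter] = {"shared": Counter(), "A-specific": Counter()}
    by_id = {c.cluster_id: c for c in clusters_a}
    for cid, label in labels.items():
        cat = by_id[cid].category_mode
        out[label][cat.value if cat else "NA"] += 1
    return out
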