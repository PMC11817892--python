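"""R-gene category assignment and protein composition features.

NLR-type disease-resistance genes are grouped into eight categories by
domain architecture.  Every category requires the central NB-ARC
nucleotide-binding domain; the N-terminal domain (TIR, CC or RPW8) and
the presence of an LRR distinguish the rest:

    NB   = NB-ARC alone            NL   = NB-ARC + LRR
    TN   = TIR + NB-ARC            TNL  = TIR + NB-ARC + LRR
    CN   = CC + NB-ARC             CNL  = CC + NB-ARC + LRR
    RN   = RPW8 + NB-ARC           RNL  = RPW8 + NB-ARC + LRR

Category coherence is validated by embedding per-protein composition
features (CKSAAP, DPC, KSCTriad) with PCA and scoring label separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_io import DomainHit, GeneModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: conjoint 7-class grouping by hydrophobicity/volume (conjoint-triad scheme)
CONJOINT_CLASSES = {
    **{aa: 0 for aa in "AGV"},
    **{aa: 1 for aa in "ILFP"},
    **{aa: 2 for aa in "YMTS"},
    **{aa: 3 for aa in "HNQW"},
    **{aa: 4 for aa in "RK"},
    **{aa: 5 for aa in "DE"},
    **{aa: 6 for aa in "C"},
}


class RCategory(str, Enum):
    TN = "TN"
    CN = "CN"
    NL = "NL"
    CNL = "CNL"
    NB = "NB"
    TNL = "TNL"
    RN = "RN"
    RNL = "RNL"

    @classmethod
    def parse(cls, name: str) -> "RCategory":
        if name.upper() == "NBS":  # accepted alias for the NB-ARC-only category
            return cls.NB
        return cls(name.upper())


#: the N-terminal domain -> category-prefix table; precedence TIR > RPW8 > CC
_NTERM_PRECEDENCE = (("TIR", "T"), ("RPW8", "R"), ("CC", "C"))

_CATEGORY_BY_KEY = {
    ("", False): RCategory.NB,
    ("", True): RCategory.NL,
    ("T", False): RCategory.TN,
    ("T", True): RCategory.TNL,
    ("C", False): RCategory.CN,
    ("C", True): RCategory.CNL,
    ("R", False): RCategory.RN,
    ("R", True): RCategory.RNL,
}


@dataclass
class Classification:
    category: Optional[RCategory]
    ambiguous: bool  # >= 2 of {TIR, CC, RPW8} present (resolved by precedence)


@dataclass
class RGene:
    gene: GeneModel
    domains: frozenset[str]
    category: RCategory
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if "NB-ARC" not in self.domains:
            raise ValueError(f"R gene {self.gene.gene_id} lacks NB-ARC")


def classify_domains(domains: Iterable[str]) -> Optional[RCategory]:
    """Map a domain set to one of the eight R-gene categories.

    Sets lacking NB-ARC are not R genes and map to None.  Sets with two
    or more N-terminal domains are resolved by precedence TIR > RPW8 > CC
    (use :func:`classify_domains_detailed` to see the ambiguity flag).
    """
    return classify_domains_detailed(domains).category


def classify_domains_detailed(domains: Iterable[str]) -> Classification:
    dset = set(domains)
    if "NB-ARC" not in dset:
        return Classification(None, False)
    nterms = [prefix for name, prefix in _NTERM_PRECEDENCE if name in dset]
    key = (nterms[0] if nterms else "", "LRR" in dset)
    return Classification(_CATEGORY_BY_KEY[key], len(nterms) >= 2)


def classify_genes(
    genes: Sequence[GeneModel],
    hits: Sequence[DomainHit],
    evalue_cutoff: float = 1e-5,
) -> list[RGene]:
    """Classify genes into R-gene categories from their filtered domain hits."""
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue <= evalue_cutoff:
            by_gene.setdefault(h.gene_id, set()).add(h.domain)
    out = []
    for g in genes:
        dset = by_gene.get(g.gene_id)
        if not dset:
            continue
        cls = classify_domains_detailed(dset)
        if cls.category is not None:
            out.append(RGene(g, frozenset(dset), cls.category, cls.ambiguous))
    return out


# ---------------------------------------------------------------------------
# Composition features


@dataclass
class FeatureVector:
    gene_id: str
    scheme: str  # "CKSAAP", "DPC" or "KSCTriad"
    k: int
    values: np.ndarray


class EmptyFeatureError(ValueError):
    """Sequence too short to yield a single countable unit."""


def _clean(seq: str) -> str:
    # non-canonical residues (X, B, Z, U, ...) are dropped from counting
    return "".join(c for c in seq.upper() if c in AMINO_ACIDS)


def extract_features(
    protein_seq: str, scheme: str, k: int = 0, gene_id: str = ""
) -> FeatureVector:
    """Extract one composition feature vector from a protein sequence.

    CKSAAP(k): frequencies of the 400 ordered residue pairs separated by
    exactly k positions, normalised by (L-k-1).  DPC is CKSAAP(0).
    KSCTriad(k): residues mapped to 7 conjoint classes; frequencies of
    the 343 class triads with spacing k, normalised by the triad count.
    """
    seq = _clean(protein_seq)
    L = len(seq)
    if scheme in ("CKSAAP", "DPC"):
        if scheme == "DPC":
            k = 0
        n_pairs = L - k - 1
        if n_pairs < 1:
            raise EmptyFeatureError(
                f"gene {gene_id or '<unnamed>'}: sequence of {L} canonical "
                f"residues admits no k={k} spaced pair"
            )
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        vec = np.zeros(400)
        for i in range(n_pairs):
            vec[idx[seq[i]] * 20 + idx[seq[i + k + 1]]] += 1
        return FeatureVector(gene_id, scheme, k, vec / n_pairs)
    if scheme == "KSCTriad":
        step = k + 1
        n_triads = L - 2 * step
        if n_triads < 1:
            raise EmptyFeatureError(
                f"gene {gene_id or '<unnamed>'}: sequence of {L} canonical "
                f"residues admits no k={k} spaced triad"
            )
        classes = [CONJOINT_CLASSES[c] for c in seq]
        vec = np.zeros(343)
        for i in range(n_triads):
            a, b, c = classes[i], classes[i + step], classes[i + 2 * step]
            vec[a * 49 + b * 7 + c] += 1
        return FeatureVector(gene_id, scheme, k, vec / n_triads)
    raise ValueError(f"unknown feature scheme {scheme!r}")


def feature_matrix(
    proteins: dict[str, str],
    schemes: Sequence[str] = ("DPC", "CKSAAP", "KSCTriad"),
    ks: Sequence[int] = (0, 1, 2, 3),
) -> tuple[list[str], np.ndarray]:
    """Concatenate per-scheme feature vectors into one matrix (genes x features)."""
    gene_ids = list(proteins)
    rows = []
    for gid in gene_ids:
        parts = []
        for scheme in schemes:
            for k in ks if scheme != "DPC" else (0,):
                parts.append(extract_features(proteins[gid], scheme, k, gid).values)
        rows.append(np.concatenate(parts))
    return gene_ids, np.vstack(rows)


def validate_categories(
    matrix: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, float]:
    """PCA-embed feature vectors to 2D and score label separation.

    Returns (n x 2 coordinates, silhouette-style score in [-1, 1]).
    Requires >= 2 labels with >= 3 members each; a constant feature
    matrix is degenerate and rejected.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    labels = list(labels)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix rows and labels must align")
    counts = {l: labels.count(l) for l in set(labels)}
    eligible = [l for l, c in counts.items() if c >= 3]
    if len(eligible) < 2:
        raise ValueError(
            "need at least two categories with >= 3 members each "
            f"(got {counts})"
        )
    if np.allclose(matrix.std(axis=0), 0.0):
        raise ValueError("degenerate input: constant feature matrix")
    coords = PCA(n_components=2, random_state=0).fit_transform(matrix)
    score = float(silhouette_score(coords, labels))
    return coords, score


def all_category_domain_sets() -> dict[frozenset[str], RCategory]:
    """The eight unambiguous domain sets and their categories (for reporting)."""
    out = {}
    for nterm, lrr in product(["", "TIR", "CC", "RPW8"], [False, True]):
        dset = frozenset({"NB-ARC"} | ({nterm} if nterm else set()) | ({"LRR"} if lrr else set()))
        out[dset] = classify_domains(dset)
    return out
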