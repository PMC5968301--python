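"""16S rRNA identity, taxonomy thresholds, OTU clustering and NJ trees.

Species/genus calls follow the conventional identity cutoffs for near
full-length 16S sequences: >=98.7% identity to a type-strain reference for
a species-level call, >95% for genus level, otherwise unclassified.  OTUs
are formed by average-linkage clustering of pairwise distances at a
similarity threshold (default 99%), with the representative of each OTU
the member minimizing the summed distance to its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Seq16S",
    "TaxonomyCall",
    "OTUSet",
    "read_fasta",
    "write_fasta",
    "pairwise_identity",
    "classify_16s",
    "cluster_otus",
    "nj_tree",
    "SPECIES_IDENTITY",
    "GENUS_IDENTITY",
]

SPECIES_IDENTITY = 98.7  # % identity for a species-level 16S call
GENUS_IDENTITY = 95.0    # % identity (strict >) for a genus-level call
DEFAULT_OTU_SIMILARITY = 0.99

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class Seq16S:
    """A 16S rRNA sequence record (IUPAC DNA alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TaxonomyCall:
    query_id: str
    best_ref_id: str
    percent_identity: float
    level: str  # "species" | "genus" | "unclassified"


@dataclass
class OTUSet:
    threshold: float
    clusters: list[list[str]]
    representatives: list[str] = field(default_factory=list)


def read_fasta(path) -> list[Seq16S]:
    return [Seq16S(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Sequence[Seq16S], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 70):
                fh.write(s.sequence[i: i + 70] + "\n")


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _identity_from_alignment(row_a: str, row_b: str,
                             count_terminal_gaps: bool = False) -> float:
    """Percent identity over aligned columns, excluding terminal-gap columns.

    Internal gap columns count in the denominator (as mismatch columns).
    """
    def span(row: str) -> tuple[int, int]:
        start = len(row) - len(row.lstrip("-"))
        end = len(row.rstrip("-"))
        return start, end

    a0, a1 = span(row_a)
    b0, b1 = span(row_b)
    if count_terminal_gaps:
        start, end = 0, len(row_a)
    else:
        start, end = max(a0, b0), min(a1, b1)
    if end <= start:
        return 0.0
    matches = sum(1 for i in range(start, end)
                  if row_a[i] == row_b[i] and row_a[i] != "-")
    return 100.0 * matches / (end - start)


def _raw_identity(a: str, b: str, aligner: Align.PairwiseAligner,
                  count_terminal_gaps: bool) -> float:
    aln = aligner.align(a, b)[0]
    return _identity_from_alignment(str(aln[0]), str(aln[1]), count_terminal_gaps)


def pairwise_identity(
    a: Seq16S | str,
    b: Seq16S | str,
    *,
    check_orientation: bool = True,
    flip_threshold: float = 60.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    count_terminal_gaps: bool = False,
) -> float:
    """Global-alignment percent identity between two sequences.

    Identity is matches over aligned columns, terminal-gap columns excluded
    (configurable).  When the identity in the given orientation falls below
    ``flip_threshold`` the reverse complement of ``b`` is also aligned and
    the better value returned — the standard orientation check for Sanger
    reads.  A gapped global alignment of unrelated nucleotide sequences
    scores ~50%, so the trigger sits above that; the maximum over the two
    orientations means a correctly oriented pair is never down-scored.
    """
    sa = a.sequence if isinstance(a, Seq16S) else str(a).upper()
    sb = b.sequence if isinstance(b, Seq16S) else str(b).upper()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    ident = _raw_identity(sa, sb, aligner, count_terminal_gaps)
    if check_orientation and ident < flip_threshold:
        flipped = str(Seq(sb).reverse_complement())
        ident = max(ident, _raw_identity(sa, flipped, aligner, count_terminal_gaps))
    return ident


def classify_16s(
    query: Seq16S,
    refs: Sequence[Seq16S],
    *,
    species_identity: float = SPECIES_IDENTITY,
    genus_identity: float = GENUS_IDENTITY,
    **identity_kwargs,
) -> TaxonomyCall:
    """Assign a taxonomy level from the best-matching type-strain reference.

    Ties on identity are broken lexicographically by reference id.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("reference set is empty")
    best_id, best_ident = None, -1.0
    for ref in sorted(refs, key=lambda r: r.id):
        ident = pairwise_identity(query, ref, **identity_kwargs)
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    if best_ident >= species_identity:
        level = "species"
    elif best_ident > genus_identity:
        level = "genus"
    else:
        level = "unclassified"
    return TaxonomyCall(query.id, best_id, best_ident, level)


def cluster_otus(
    seqs: Sequence[Seq16S],
    similarity: float = DEFAULT_OTU_SIMILARITY,
    **identity_kwargs,
) -> OTUSet:
    """Cluster sequences into OTUs at a similarity threshold.

    Distances are 1 - identity/100; clusters are cut from an
    average-linkage tree at 1 - similarity.  Each OTU's representative is
    the member with minimum summed distance to the rest of its cluster
    (ties broken lexicographically by id).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids = [s.id for s in seqs]
    n = len(seqs)
    if n == 1:
        return OTUSet(similarity, [[ids[0]]], [ids[0]])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(seqs[i], seqs[j], **identity_kwargs) / 100.0
            dist[i, j] = dist[j, i] = d
    merge = linkage(squareform(dist, checks=False), method="average")
    cut = 1.0 - similarity
    assignment = fcluster(merge, t=cut, criterion="distance")
    clusters: list[list[str]] = []
    reps: list[str] = []
    for label in np.unique(assignment):
        members = [i for i in range(n) if assignment[i] == label]
        rep = min(members, key=lambda i: (dist[i, members].sum(), ids[i]))
        clusters.append(sorted(ids[i] for i in members))
        reps.append(ids[rep])
    order = np.argsort([c[0] for c in clusters])
    return OTUSet(similarity, [clusters[i] for i in order], [reps[i] for i in order])


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree from a distance matrix, returned as newick.

    Pair selection minimizes the Q criterion with deterministic tie-breaks
    by label order.  Negative branch lengths are clamped to zero with the
    deficit shifted to the sister branch (pairwise path lengths are
    preserved), so additive matrices are reproduced exactly.
    """
    D = np.asarray(dist, float).copy()
    labels = [str(x) for x in labels]
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("at least three taxa are required")

    nodes = list(labels)            # newick fragment per active node
    keys = list(labels)             # lexicographic tie-break key per node

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li  # shift the deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_node = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        new_key = min(keys[i], keys[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [new_key]

    d = D[0, 1]
    return f"({nodes[0]}:{fmt(d / 2)},{nodes[1]}:{fmt(d / 2)});"


def nj_tree_from_seqs(seqs: Sequence[Seq16S], **identity_kwargs) -> str:
    """Convenience: NJ tree on 1 - identity distances between sequences."""
    seqs = list(seqs)
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(seqs[i], seqs[j], **identity_kwargs) / 100.0
            D[i, j] = D[j, i] = d
    return nj_tree(D, [s.id for s in seqs])
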