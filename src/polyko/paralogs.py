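"""Paralog discovery in a (possibly polyploid) genome.

Polyploid crop genomes carry several near-identical copies of most genes
(in tetraploid *Brassica napus*, typically one per subgenome and more
after segmental duplication; within-family nucleotide identity is
usually in the high-80s to high-90s percent).  Knockout experiments must
therefore first enumerate the whole gene family.  This module finds
paralogous copies of a query CDS by k-mer-seeded alignment, computes the
within-family identity matrix, clusters records into families, and
builds a neighbor-joining tree as a quick phylogenetic summary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from polyko._seq import revcomp

__all__ = [
    "ParalogRecord",
    "GeneFamily",
    "find_paralogs",
    "pairwise_identity",
    "pairwise_identity_matrix",
    "group_families",
    "build_distance_tree",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ParalogRecord:
    """A gene copy located on a genome contig.

    Ids follow the ``Gene.SubgenomeChromosome`` convention common in
    allopolyploid nomenclature (e.g. ``ITPK1.A10`` for the copy on
    chromosome A10).  Coordinates are 0-based half-open on the forward
    strand of ``contig``.
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_sequence: str
    identity: float | None = None  # identity to the query that found it

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GeneFamily:
    """A group of paralogs with their pairwise identity matrix."""

    name: str
    members: list[ParalogRecord]
    identity_matrix: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.identity_matrix, dtype=float)
        if m.shape != (len(self.members), len(self.members)):
            raise ValueError("identity matrix dimension != member count")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("identity matrix diagonal must be 1")
        self.identity_matrix = m

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def member(self, member_id: str) -> ParalogRecord:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (match columns, total alignment columns) of an edlib cigar."""
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences.

    Identity is matches over total alignment columns; gap columns count
    as mismatches, so a 10-nt sequence with one terminal indel against
    an 11-nt one scores 10/11, not 10/10.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    return matches / columns


def pairwise_identity_matrix(members) -> np.ndarray:
    """Symmetric matrix of global-alignment identities.

    ``members`` may be sequences or :class:`ParalogRecord` objects.
    """
    seqs = [m.cds_sequence if isinstance(m, ParalogRecord) else m for m in members]
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 members")
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(seqs[i], seqs[j])
    return mat


def _scan_contig_strand(
    query: str, contig: str, min_identity: float, min_coverage: float,
    max_hits: int = 100,
) -> list[tuple[int, float, int, int]]:
    """All non-overlapping query hits on one strand of one contig.

    Iterative semi-global (query-in-infix) alignment with masking: the
    best remaining hit is located, recorded if it clears the identity
    and coverage floors, then masked out, until the best remaining hit
    falls below the floor.  Fully sensitive at the identity floor,
    unlike heuristic seeding.
    """
    qlen = len(query)
    masked = list(contig)
    hits: list[tuple[int, float, int, int]] = []  # matches, identity, start, end
    for _ in range(max_hits):
        res = edlib.align(query, "".join(masked), mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            break
        loc0, loc1 = res["locations"][0]
        matches, columns = _cigar_stats(res["cigar"])
        identity = matches / columns
        # the whole query is aligned in HW mode; coverage is the aligned
        # query fraction (< 1 only when the contig end truncates the hit)
        coverage = min(1.0, columns / qlen)
        if identity < min_identity:
            break
        if coverage >= min_coverage:
            hits.append((matches, identity, loc0, loc1 + 1))
        for i in range(loc0, loc1 + 1):
            masked[i] = "N"
    return hits


def find_paralogs(
    query_cds: str,
    genome_contigs: dict[str, str],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[ParalogRecord]:
    """Locate paralogous copies of ``query_cds`` in a genome.

    Both strands of every contig are searched by iterative semi-global
    alignment with masking.  Hits with identity >= ``min_identity``
    covering at least ``min_coverage`` of the query are kept;
    overlapping hits are resolved in favour of the higher-scoring one.
    Results are sorted by score (match count) descending.
    """
    query_cds = query_cds.upper()
    if len(query_cds) < 60:
        raise ValueError("query too short (< 60 nt)")
    if not genome_contigs:
        raise ValueError("empty genome")

    raw_hits: list[tuple[int, float, str, int, int, str]] = []
    for contig_name, contig in genome_contigs.items():
        contig = contig.upper()
        for strand, q in (("+", query_cds), ("-", revcomp(query_cds))):
            for matches, identity, start, end in _scan_contig_strand(
                q, contig, min_identity, min_coverage
            ):
                raw_hits.append((matches, identity, contig_name, start, end, strand))

    # minus-strand hits come from aligning the reverse-complemented query
    # against the forward contig, so coordinates are already forward-strand
    hits = raw_hits

    # greedy non-overlapping selection, best score first
    hits.sort(key=lambda h: (-h[0], h[2], h[3]))
    kept: list[tuple[int, float, str, int, int, str]] = []
    for h in hits:
        overlaps = any(
            h[2] == g[2] and h[3] < g[4] and g[3] < h[4] for g in kept
        )
        if not overlaps:
            kept.append(h)

    records = []
    for i, (matches, identity, cname, start, end, strand) in enumerate(kept):
        seq = genome_contigs[cname].upper()[start:end]
        if strand == "-":
            seq = revcomp(seq)
        records.append(
            ParalogRecord(
                id=f"{cname}:{start}-{end}{strand}",
                contig=cname,
                start=start,
                end=end,
                strand=strand,
                cds_sequence=seq,
                identity=identity,
            )
        )
    return records


def group_families(
    records: list[ParalogRecord], within_threshold: float = 0.85
) -> list[GeneFamily]:
    """Single-linkage clustering of records into gene families.

    Two records join the same family whenever their global-alignment
    identity is at least ``within_threshold`` (directly or through a
    chain of intermediates).
    """
    if not records:
        raise ValueError("no records to group")
    n = len(records)
    if n == 1:
        return [GeneFamily("family1", list(records), np.eye(1))]
    mat = pairwise_identity_matrix(records)

    parent = list(range(n))

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= within_threshold:
                parent[root(i)] = root(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(root(i), []).append(i)

    families = []
    for fi, idxs in enumerate(sorted(clusters.values(), key=min), start=1):
        sub = mat[np.ix_(idxs, idxs)]
        families.append(
            GeneFamily(f"family{fi}", [records[i] for i in idxs], sub)
        )
    return families


def build_distance_tree(identity_matrix, labels: list[str]) -> str:
    """Neighbor-joining tree from an identity matrix, as Newick.

    Distance is 1 - identity.  Negative branch lengths (an artefact NJ
    can produce on non-additive data) are clamped to zero.
    """
    mat = np.asarray(identity_matrix, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("identity matrix must be square and symmetric")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != mat.shape[0]:
        raise ValueError("label count != matrix dimension")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids=list(labels)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
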