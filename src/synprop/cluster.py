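"""Sequence clustering and taxonomy assignment for 16S clone libraries.

Clone reads covering one end of the 16S gene are compared by optimal
global alignment with free terminal gaps (semi-global), the right model
for partial single-pass reads of a shared gene.  Identity is counted as
matches over alignment columns excluding terminal-gap columns (internal
gaps count as mismatch columns); coverage is the aligned span of the
query over its length.  Clusters are the single-linkage connected
components of the pairwise graph thresholded at 97% identity and 80%
coverage (in either query direction), the semantics of BLASTclust.

Representatives are the longest member of each cluster and carry the
cluster's taxonomy: the best-identity reference taxon, reported at
species rank when identity exceeds 97% and at genus rank otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "SequenceRecord",
    "PairwiseIdentity",
    "SequenceCluster",
    "ReferenceTaxon",
    "TaxonAssignment",
    "ClusterError",
    "pairwise_identity",
    "cluster_sequences",
    "assign_taxonomy",
]

_VALID = set("ACGTRYSWKMBDHVN")


class ClusterError(ValueError):
    """Raised for invalid clustering inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (a clone read or a reference gene)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        s = self.sequence.upper()
        if not s:
            raise ClusterError(f"record {self.id!r} has an empty sequence")
        bad = set(s) - _VALID
        if bad:
            raise ClusterError(f"record {self.id!r} has invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", s)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseIdentity:
    """Percent identity and percent query coverage of one comparison."""

    identity: float
    coverage: float


@dataclass
class SequenceCluster:
    """A cluster of records with its representative.

    The representative is the longest member, ties broken by
    lexicographically smallest id.
    """

    id: str
    members: dict[str, SequenceRecord]
    representative: str

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative_record(self) -> SequenceRecord:
        return self.members[self.representative]


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference sequence labelled at species and genus rank."""

    name: str
    species: str
    genus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ClusterError(f"reference {self.name!r} has an empty sequence")


@dataclass(frozen=True)
class TaxonAssignment:
    """Best-reference call for a cluster.

    rank is ``species`` iff identity > 97 (strict), else ``genus``.
    """

    cluster_id: str
    taxon: str
    identity: float
    rank: str


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    # Free terminal gaps: partial reads of one gene must not pay for the
    # unsequenced remainder.
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


_ALIGNER = _aligner()


def _align_stats(a: str, b: str) -> tuple[float, float, float]:
    """(identity %, coverage of a %, coverage of b %) for one alignment."""
    aln = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, 0.0
    matches = 0
    columns = 0
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for i in range(ea - sa):
            if a[sa + i] == b[sb + i]:
                matches += 1
        columns += ea - sa
        if prev_a is not None:
            # Internal gap columns between consecutive aligned blocks.
            columns += (sa - prev_a) + (sb - prev_b)
        prev_a, prev_b = ea, eb
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    identity = 100.0 * matches / columns
    return identity, 100.0 * span_a / len(a), 100.0 * span_b / len(b)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> PairwiseIdentity:
    """Align ``a`` (the query) to ``b`` and report identity and coverage.

    Identity excludes terminal-gap columns from the denominator; internal
    gap columns count as mismatches.  Coverage is the aligned span of the
    query divided by the query length, as percent.
    """
    identity, cov_a, _ = _align_stats(a.sequence, b.sequence)
    return PairwiseIdentity(identity, cov_a)


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def cluster_sequences(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 97.0,
    coverage_threshold: float = 80.0,
) -> list[SequenceCluster]:
    """Single-linkage clustering at identity and coverage thresholds.

    An edge joins two records when identity >= ``identity_threshold`` and
    query coverage >= ``coverage_threshold`` in either query direction,
    i.e. with each record taken as the query in turn.  Clusters are the
    connected components, sorted by decreasing size (ties by
    representative id); cluster ids are C1, C2, ...
    """
    if not records:
        raise ClusterError("no records to cluster")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ClusterError("duplicate record ids")
    uf = _UnionFind(ids)
    by_id = {r.id: r for r in records}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if uf.find(a.id) == uf.find(b.id):
                continue
            identity, cov_a, cov_b = _align_stats(a.sequence, b.sequence)
            if identity >= identity_threshold and min(cov_a, cov_b) >= coverage_threshold:
                uf.union(a.id, b.id)
    components: dict[str, list[str]] = {}
    for rid in ids:
        components.setdefault(uf.find(rid), []).append(rid)

    def rep(member_ids: list[str]) -> str:
        return min(member_ids, key=lambda m: (-len(by_id[m]), m))

    ordered = sorted(components.values(), key=lambda ms: (-len(ms), rep(ms)))
    return [
        SequenceCluster(f"C{k}", {m: by_id[m] for m in ms}, rep(ms))
        for k, ms in enumerate(ordered, start=1)
    ]


def assign_taxonomy(
    cluster: SequenceCluster,
    references: Sequence[ReferenceTaxon],
    species_identity: float = 97.0,
) -> TaxonAssignment:
    """Assign a cluster to its best reference taxon.

    The cluster representative is aligned (as query) to every reference;
    the best identity wins, ties broken by higher coverage and then by
    reference name.  Identity strictly above ``species_identity`` earns a
    species-rank call naming the reference species; anything at or below
    it falls back to genus rank.
    """
    if not references:
        raise ClusterError("empty reference set")
    query = cluster.representative_record.sequence
    best = None
    for ref in sorted(references, key=lambda r: r.name):
        identity, cov, _ = _align_stats(query, ref.sequence)
        key = (-identity, -cov, ref.name)
        if best is None or key < best[0]:
            best = (key, ref, identity)
    _, ref, identity = best
    if identity > species_identity:
        return TaxonAssignment(cluster.id, ref.species, identity, "species")
    return TaxonAssignment(cluster.id, ref.genus, identity, "genus")
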