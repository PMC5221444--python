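"""File-format plumbing: FASTA and TSV readers/writers used by the CLI."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import ReferenceTaxon, SequenceCluster, SequenceRecord, TaxonAssignment


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, description: str = "") -> None:
    seqs = [
        SeqRecord(Seq(seq), id=name, description=description) for name, seq in records
    ]
    SeqIO.write(seqs, path, "fasta")


def read_reference_fasta(path) -> list[ReferenceTaxon]:
    """References with headers ``>name species|genus``."""
    refs = []
    for rec in SeqIO.parse(path, "fasta"):
        desc = rec.description.split(None, 1)
        if len(desc) < 2 or "|" not in desc[1]:
            raise ValueError(
                f"reference {rec.id!r} must carry a 'species|genus' label"
            )
        species, genus = desc[1].split("|", 1)
        refs.append(ReferenceTaxon(rec.id, species.strip(), genus.strip(), str(rec.seq)))
    return refs


def clusters_to_frame(clusters: Sequence[SequenceCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": cl.id,
            "member_id": mid,
            "is_representative": mid == cl.representative,
        }
        for cl in clusters
        for mid in sorted(cl.members)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "member_id", "is_representative"])


def assignments_to_frame(assignments: Sequence[TaxonAssignment]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": a.cluster_id,
            "taxon": a.taxon,
            "identity": round(a.identity, 2),
            "rank": a.rank,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "taxon", "identity", "rank"])
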