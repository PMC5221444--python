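"""In-silico PCR and ARDRA fingerprinting.

Clone libraries of 16S rRNA genes are built by domain-specific PCR with
degenerate primers, and clones are pre-sorted by amplified rDNA restriction
analysis (ARDRA): each clone's amplicon is digested in separate reactions,
the fragment patterns are read off a gel, and clones sharing the same
pattern in every assay form one ARDRA group.  This module simulates all of
that on plain nucleotide strings: IUPAC-aware primer-site scanning with a
strict 3'-anchor, amplicon extraction, restriction digestion with a small
enzyme registry, gel-resolution binning, and pattern grouping.

Molecules are treated as linear double-stranded DNA.  The packaged enzymes
all have reverse-complement-palindromic recognition sites, so scanning the
top strand finds every cut; this is asserted when the registry loads.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import yaml
from Bio.Seq import Seq

__all__ = [
    "IUPAC",
    "Primer",
    "Amplicon",
    "RestrictionEnzyme",
    "DigestPattern",
    "ArdraProfile",
    "ArdraGroup",
    "AmpliconError",
    "reverse_complement",
    "find_primer_sites",
    "simulate_pcr",
    "digest",
    "gel_bin",
    "group_profiles",
    "load_enzymes",
    "load_primers",
    "BACTERIAL_ASSAYS",
    "ARCHAEAL_ASSAYS",
]

#: 15-letter IUPAC nucleotide alphabet mapped to the bases each code allows.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class AmpliconError(ValueError):
    """Raised for invalid sequences, primers or enzyme definitions."""


def _validate(seq: str, what: str) -> str:
    s = seq.upper()
    bad = set(s) - set(IUPAC)
    if bad:
        raise AmpliconError(f"invalid IUPAC character(s) {sorted(bad)} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement of a nucleotide string."""
    return str(Seq(_validate(seq, "sequence")).reverse_complement())


def _compatible(code_a: str, code_b: str) -> bool:
    """Two IUPAC codes are compatible when their base sets intersect."""
    return bool(IUPAC[code_a] & IUPAC[code_b])


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3' in the IUPAC alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AmpliconError(f"primer {self.name!r} is empty")
        object.__setattr__(self, "sequence", _validate(self.sequence, f"primer {self.name}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product located on its template.

    ``start``/``end`` are 0-based half-open coordinates on the top strand
    of the template; ``sequence`` is the product read 5'->3' on ``strand``
    and includes both primer-binding regions.
    """

    source_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AmpliconError("amplicon coordinates must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise AmpliconError("strand must be '+' or '-'")
        if len(self.sequence) != self.end - self.start:
            raise AmpliconError("amplicon sequence length must equal end - start")

    def __len__(self) -> int:
        return self.end - self.start


def _scan_one_strand(template: str, primer: str, max_mismatch: int):
    """Yield (pos, mismatches) for primer matches on the given strand.

    The primer's 3'-terminal base must be IUPAC-compatible with the
    template (mimicking the polymerase-extension requirement); mismatches
    elsewhere are counted against ``max_mismatch``.
    """
    k = len(primer)
    for i in range(len(template) - k + 1):
        if not _compatible(primer[-1], template[i + k - 1]):
            continue
        mm = 0
        for j in range(k - 1):
            if not _compatible(primer[j], template[i + j]):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            yield i, mm


def find_primer_sites(
    template: str, primer: Primer, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """All primer binding sites on both strands of a template.

    Returns (position, strand, mismatches) tuples.  ``position`` is the
    0-based start of the matched window in top-strand coordinates; strand
    '+' means the primer matches the window directly, '-' that it matches
    the window's reverse complement.  The 3'-terminal primer base must
    match exactly (it never counts toward the mismatch allowance).
    """
    if max_mismatch < 0:
        raise AmpliconError("max_mismatch must be >= 0")
    t = _validate(template, "template")
    if not t:
        raise AmpliconError("template is empty")
    hits = [(pos, "+", mm) for pos, mm in _scan_one_strand(t, primer.sequence, max_mismatch)]
    rc = reverse_complement(t)
    k = len(primer)
    for pos, mm in _scan_one_strand(rc, primer.sequence, max_mismatch):
        hits.append((len(t) - pos - k, "-", mm))
    return sorted(hits)


def _pair_amplicons(template: str, forward: Primer, reverse: Primer, max_mismatch: int):
    """Plus-strand products: forward '+' hits paired with the nearest
    downstream '-' hit of the reverse primer whose product is in bounds."""
    fwd = [h for h in find_primer_sites(template, forward, max_mismatch) if h[1] == "+"]
    rev = [h for h in find_primer_sites(template, reverse, max_mismatch) if h[1] == "-"]
    for fpos, _, _ in fwd:
        for rpos, _, _ in sorted(rev):
            end = rpos + len(reverse)
            if rpos >= fpos and end > fpos + len(forward):
                yield fpos, end
                break


def simulate_pcr(
    template: str,
    forward: Primer,
    reverse: Primer,
    length_bounds: tuple[int, int] = (200, 5000),
    max_mismatch: int = 0,
    source_id: str = "template",
) -> list[Amplicon]:
    """In-silico PCR on a linear template.

    One amplicon per (forward hit, nearest downstream reverse-complemented
    reverse hit) pair whose product length is within ``length_bounds``.
    Both template strands are considered; products on the '-' strand carry
    mirrored top-strand coordinates.  No hits yield an empty list.
    """
    lo, hi = length_bounds
    if lo <= 0 or lo > hi:
        raise AmpliconError("length bounds must be positive with min <= max")
    t = _validate(template, "template")
    products: list[Amplicon] = []
    for start, end in _pair_amplicons(t, forward, reverse, max_mismatch):
        if lo <= end - start <= hi:
            products.append(Amplicon(source_id, start, end, "+", t[start:end]))
    rc = reverse_complement(t)
    for start, end in _pair_amplicons(rc, forward, reverse, max_mismatch):
        if lo <= end - start <= hi:
            products.append(
                Amplicon(source_id, len(t) - end, len(t) - start, "-", rc[start:end])
            )
    return products


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC recognition site and top-strand
    cut offset (0 .. len(recognition))."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise AmpliconError(f"enzyme {self.name!r} has empty recognition site")
        object.__setattr__(
            self, "recognition", _validate(self.recognition, f"enzyme {self.name}")
        )
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise AmpliconError(f"enzyme {self.name!r} cut offset out of range")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


@dataclass(frozen=True)
class DigestPattern:
    """Fragment lengths from one digestion assay.

    Straight out of :func:`digest` the lengths sum to the digested
    sequence length; after :func:`gel_bin` they are gel bands (descending,
    sub-detection fragments dropped, co-migrating fragments merged).
    """

    assay_id: str
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise AmpliconError("fragment lengths must be positive")
        object.__setattr__(self, "fragment_lengths", tuple(self.fragment_lengths))


@dataclass(frozen=True)
class ArdraProfile:
    """Per-clone ordered list of binned digest patterns, one per assay."""

    clone_id: str
    patterns: tuple[DigestPattern, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", tuple(self.patterns))

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(p.assay_id for p in self.patterns)

    def key(self) -> str:
        """Canonical serialization used as the grouping key."""
        return ";".join(
            f"{p.assay_id}:" + ",".join(map(str, p.fragment_lengths))
            for p in self.patterns
        )


@dataclass
class ArdraGroup:
    """Clones sharing an identical binned restriction profile."""

    key: str
    members: list[str]

    @property
    def representative(self) -> str:
        """First member in input order (the clone picked for sequencing)."""
        return self.members[0]


def _site_starts(seq: str, recognition: str) -> list[int]:
    k = len(recognition)
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(_compatible(recognition[j], seq[i + j]) for j in range(k))
    ]


def digest(
    sequence: str,
    enzymes: Sequence[RestrictionEnzyme],
    assay_id: str | None = None,
) -> DigestPattern:
    """Digest a linear sequence with one or more enzymes in one reaction.

    Cut positions are the union over enzymes of (site start + cut offset)
    on the top strand; overlapping sites all count and coincident cuts are
    deduplicated.  Fragment lengths are the sorted gaps between
    consecutive cuts and the sequence ends, and always sum to the input
    length.
    """
    if not enzymes:
        raise AmpliconError("digest needs at least one enzyme")
    s = _validate(sequence, "sequence")
    if not s:
        raise AmpliconError("cannot digest an empty sequence")
    cuts: set[int] = set()
    for enz in enzymes:
        for start in _site_starts(s, enz.recognition):
            pos = start + enz.cut_offset
            if 0 < pos < len(s):
                cuts.add(pos)
    bounds = [0, *sorted(cuts), len(s)]
    frags = sorted(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestPattern(assay_id or "+".join(e.name for e in enzymes), tuple(frags))


def gel_bin(
    pattern: DigestPattern,
    relative_tolerance: float = 0.05,
    detection_limit: int = 50,
) -> DigestPattern:
    """Collapse a digest pattern to what a 2% agarose gel resolves.

    Fragments below ``detection_limit`` nt run off or stain too weakly and
    are dropped; the rest are sorted descending and adjacent lengths
    differing by less than ``relative_tolerance`` times the larger length
    co-migrate and merge into one band, reported as the rounded mean of
    its members.
    """
    if relative_tolerance < 0 or detection_limit < 0:
        raise AmpliconError("tolerance and detection limit must be >= 0")
    frags = sorted((f for f in pattern.fragment_lengths if f >= detection_limit), reverse=True)
    bands: list[list[int]] = []
    for f in frags:
        if bands and (bands[-1][-1] - f) < relative_tolerance * bands[-1][-1]:
            bands[-1].append(f)
        else:
            bands.append([f])
    merged = tuple(round(sum(b) / len(b)) for b in bands)
    return DigestPattern(pattern.assay_id, merged)


def group_profiles(profiles: Sequence[ArdraProfile]) -> list[ArdraGroup]:
    """Partition clones by exact equality of their binned profiles.

    All profiles must carry the same ordered assay list.  Groups are
    returned in order of first appearance.
    """
    if not profiles:
        return []
    assays = profiles[0].assay_ids
    groups: dict[str, ArdraGroup] = {}
    for prof in profiles:
        if prof.assay_ids != assays:
            raise AmpliconError(
                f"clone {prof.clone_id!r} has assay list {prof.assay_ids}, "
                f"expected {assays}"
            )
        key = prof.key()
        if key not in groups:
            groups[key] = ArdraGroup(key, [])
        groups[key].members.append(prof.clone_id)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Packaged registries


def _load_packaged(name: str):
    ref = resources.files("synprop.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_enzymes(path=None) -> dict[str, RestrictionEnzyme]:
    """Enzyme registry (packaged default or user YAML).

    Every packaged enzyme's recognition site must be its own reverse
    complement, the property that lets one-strand scanning find all
    double-strand cuts; this is asserted here.
    """
    docs = _load_packaged("enzymes.yaml") if path is None else yaml.safe_load(open(path))
    reg = {}
    for doc in docs["enzymes"]:
        enz = RestrictionEnzyme(doc["name"], doc["recognition"], int(doc["cut_offset"]))
        if not enz.is_palindromic:
            raise AmpliconError(
                f"enzyme {enz.name!r} recognition site is not reverse-complement "
                "palindromic; one-strand scanning would miss cuts"
            )
        reg[enz.name] = enz
    return reg


def load_primers(path=None) -> dict[str, Primer]:
    """Primer registry (packaged default or user YAML)."""
    docs = _load_packaged("primers.yaml") if path is None else yaml.safe_load(open(path))
    return {doc["name"]: Primer(doc["name"], doc["sequence"]) for doc in docs["primers"]}


def BACTERIAL_ASSAYS() -> list[list[RestrictionEnzyme]]:
    """The two separate bacterial ARDRA reactions: HhaI, then HinfI."""
    enz = load_enzymes()
    return [[enz["HhaI"]], [enz["HinfI"]]]


def ARCHAEAL_ASSAYS() -> list[list[RestrictionEnzyme]]:
    """The two archaeal ARDRA reactions: HaeIII, then SmaI + XhoI together."""
    enz = load_enzymes()
    return [[enz["HaeIII"]], [enz["SmaI"], enz["XhoI"]]]


def ardra_profile(
    clone_id: str,
    sequence: str,
    assays: Sequence[Sequence[RestrictionEnzyme]],
    relative_tolerance: float = 0.05,
    detection_limit: int = 50,
) -> ArdraProfile:
    """Digest one clone in every assay and bin each pattern for the gel."""
    patterns = tuple(
        gel_bin(digest(sequence, list(a)), relative_tolerance, detection_limit)
        for a in assays
    )
    return ArdraProfile(clone_id, patterns)
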