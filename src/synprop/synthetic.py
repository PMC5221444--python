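"""Seeded mock datasets with the statistical structure the pipeline assumes.

No real sequence data are required anywhere: this module fabricates marker
genes that the packaged primers amplify, with planted cluster structure
(taxa separated by a controlled divergence, clone-level variation well
below it), samples clone libraries multinomially from time-varying
community compositions, generates single-pass reads covering the 5' or 3'
end of the amplicon (747-1141 nt), and produces first-order propionate
decay curves with optional lag or failure.

Determinism contract: every operation takes an integer seed and derives an
independent numpy Generator from it; identical seeds give byte-identical
datasets.  The mutation model is independent uniform substitution (no
indels), which keeps identity arithmetic exact for tests; primer-binding
regions are never mutated (the universal-primer conservation assumption).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, exp
from typing import Mapping, Sequence

import numpy as np

from . import amplicon as amp
from . import cluster as clu
from . import community as comm

__all__ = [
    "MockTaxon",
    "DecayParameters",
    "CommunityScenario",
    "MockClone",
    "MockCloneLibrary",
    "RecoveryReport",
    "SyntheticError",
    "READ_LENGTH_RANGE",
    "make_reference_community",
    "make_variants",
    "make_scenario",
    "sample_clone_library",
    "simulate_degradation",
    "run_round_trip",
]

#: Single-pass Sanger read lengths (nt) emulated by the generator.
READ_LENGTH_RANGE = (747, 1141)

#: Default mock marker gene length (nt), in the range of a full 16S gene.
GENE_LENGTH = 1500

_BASES = np.array(list("ACGT"))


class SyntheticError(ValueError):
    """Raised for unattainable generator constraints."""


@dataclass(frozen=True)
class MockTaxon:
    """A mock community member: name, functional guild and a full marker
    gene carrying the forward primer site at the 5' end and the reverse
    complement of the reverse primer at the 3' end."""

    name: str
    guild: str
    gene: str


@dataclass(frozen=True)
class DecayParameters:
    """First-order propionate decay: c(t) = initial * exp(-rate * max(0, t - lag)).

    ``failure`` models a stalled batch: the rate is forced to zero and
    only small seeded measurement jitter remains.
    """

    initial_mM: float = 25.0
    rate_per_day: float = 0.08
    lag_days: float = 0.0
    failure: bool = False

    def __post_init__(self) -> None:
        if self.rate_per_day < 0:
            raise SyntheticError("decay rate must be non-negative")
        if self.initial_mM <= 0:
            raise SyntheticError("initial concentration must be positive")


@dataclass(frozen=True)
class CommunityScenario:
    """A complete mock study condition for one consortium.

    ``compositions`` maps timepoint labels (t1-t3) to probability vectors
    over ``taxa``; ``within_divergence`` is the per-site substitution rate
    applied to each clone relative to its taxon gene.
    """

    label: str
    taxa: tuple[MockTaxon, ...]
    compositions: Mapping[str, tuple[float, ...]]
    decay: DecayParameters
    seed: int
    within_divergence: float = 0.01

    def __post_init__(self) -> None:
        comps = {}
        for tp, p in self.compositions.items():
            vec = tuple(float(x) for x in p)
            if len(vec) != len(self.taxa):
                raise SyntheticError(f"composition at {tp} has wrong length")
            if any(x < 0 for x in vec):
                raise SyntheticError("composition probabilities must be >= 0")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise SyntheticError(f"composition at {tp} does not sum to 1")
            comps[tp] = vec
        object.__setattr__(self, "compositions", comps)
        object.__setattr__(self, "taxa", tuple(self.taxa))


@dataclass(frozen=True)
class MockClone:
    """One sampled clone: its true taxon, the full (mutated) insert
    sequence and the single-pass read (a contiguous window covering the
    5' or 3' end of the insert)."""

    clone_id: str
    taxon: str
    sequence: str
    read: str


@dataclass(frozen=True)
class MockCloneLibrary:
    """A clone library for one (scenario, timepoint) sample."""

    sample_label: str
    clones: tuple[MockClone, ...]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _resolve_iupac(rng: np.random.Generator, sequence: str) -> str:
    """Replace degenerate codes by a concrete base each code allows."""
    out = []
    for c in sequence:
        allowed = sorted(amp.IUPAC[c])
        out.append(allowed[rng.integers(0, len(allowed))])
    return "".join(out)


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    positions: np.ndarray,
) -> str:
    """Substitute the given positions with a uniformly drawn other base."""
    seq = np.array(list(sequence))
    for pos in positions:
        current = seq[pos]
        choices = [b for b in "ACGT" if b != current]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def make_reference_community(
    n_taxa: int,
    between_divergence: float = 0.10,
    within_divergence: float = 0.01,
    primer_pair: tuple[amp.Primer, amp.Primer] | None = None,
    seed: int = 0,
    gene_length: int = GENE_LENGTH,
) -> list[MockTaxon]:
    """Plant ``n_taxa`` mock marker genes with controlled divergence.

    A random ancestor gene is built as (resolved forward primer site) +
    random core + (reverse complement of resolved reverse primer), then
    each taxon mutates its own disjoint set of core positions, so realized
    pairwise divergences are exactly twice the per-taxon mutation load:
    at least ``between_divergence`` and at most 0.3 of the gene length.
    Primer sites are left untouched and remain findable at 0 mismatches.
    Guilds are assigned cyclically from the five-guild vocabulary.
    """
    if n_taxa < 1:
        raise SyntheticError("n_taxa must be >= 1")
    if not (0 <= within_divergence < between_divergence <= 0.3):
        raise SyntheticError("need 0 <= within < between <= 0.3")
    if primer_pair is None:
        primers = amp.load_primers()
        primer_pair = (primers["E5F"], primers["E1541r"])
    fwd, rev = primer_pair
    rng = _rng(seed, 0)
    fwd_site = _resolve_iupac(rng, fwd.sequence)
    rev_site = amp.reverse_complement(_resolve_iupac(rng, rev.sequence))
    core_len = gene_length - len(fwd_site) - len(rev_site)
    if core_len <= 0:
        raise SyntheticError("gene_length too short for the primer pair")
    ancestor = fwd_site + _random_seq(rng, core_len) + rev_site
    core = np.arange(len(fwd_site), len(fwd_site) + core_len)

    # Disjoint per-taxon mutation sets: pairwise divergence = 2k / L.
    # k is chosen so 2k/L lands at 1.25x the requested floor, capped at 0.3.
    target = min(1.25 * between_divergence, 0.3)
    k = ceil(target * gene_length / 2)
    if 2 * k / gene_length < between_divergence:
        k = ceil(between_divergence * gene_length / 2)
    if n_taxa * k > core_len:
        raise SyntheticError(
            f"cannot plant {n_taxa} taxa at divergence {between_divergence} "
            f"in a {gene_length} nt gene (mutable core too small)"
        )
    shuffled = rng.permutation(core)
    taxa = []
    for i in range(n_taxa):
        positions = np.sort(shuffled[i * k : (i + 1) * k])
        gene = _mutate(rng, ancestor, positions)
        taxa.append(
            MockTaxon(
                name=f"taxon{i + 1}",
                guild=comm.GUILDS[i % len(comm.GUILDS)],
                gene=gene,
            )
        )
    return taxa


def make_variants(
    taxon: MockTaxon,
    n_variants: int,
    divergence: float,
    seed: int = 0,
    protect_primers: int = 20,
) -> list[clu.SequenceRecord]:
    """Full-length within-cluster variants of one taxon gene.

    Each variant substitutes a fresh random fraction ``divergence`` of the
    positions outside the terminal ``protect_primers`` nucleotides.
    """
    rng = _rng(seed, 7)
    gene = taxon.gene
    mutable = np.arange(protect_primers, len(gene) - protect_primers)
    k = round(divergence * len(gene))
    out = []
    for i in range(n_variants):
        positions = rng.choice(mutable, size=k, replace=False)
        out.append(
            clu.SequenceRecord(f"{taxon.name}_v{i + 1}", _mutate(rng, gene, positions))
        )
    return out


def make_scenario(
    label: str = "mock",
    n_taxa: int = 5,
    seed: int = 0,
    compositions: Mapping[str, Sequence[float]] | None = None,
    decay: DecayParameters | None = None,
    between_divergence: float = 0.10,
    within_divergence: float = 0.01,
) -> CommunityScenario:
    """Convenience constructor for a full study condition.

    Without explicit compositions, per-timepoint community compositions
    are drawn from a flat Dirichlet, emulating succession by resampling
    each timepoint independently.
    """
    taxa = make_reference_community(
        n_taxa,
        between_divergence=between_divergence,
        within_divergence=within_divergence,
        seed=seed,
    )
    if compositions is None:
        rng = _rng(seed, 1)
        compositions = {
            tp: tuple(rng.dirichlet(np.ones(n_taxa))) for tp in comm.TIMEPOINTS
        }
    return CommunityScenario(
        label=label,
        taxa=tuple(taxa),
        compositions=compositions,
        decay=decay or DecayParameters(),
        seed=seed,
        within_divergence=within_divergence,
    )


def sample_clone_library(
    scenario: CommunityScenario,
    timepoint: str,
    n_clones: int = 60,
    seed: int | None = None,
    read_direction: str = "5p",
) -> MockCloneLibrary:
    """Draw a clone library multinomially from one timepoint's composition.

    Each clone is a copy of its taxon's gene with substitutions at the
    scenario's within-cluster rate (primer sites excluded), plus a
    single-pass read: a window of seeded random length within
    ``READ_LENGTH_RANGE`` anchored at the 5' end, the 3' end, or either at
    random (``read_direction`` in {"5p", "3p", "mixed"}).  Mixed-direction
    read sets should be clustered per direction, as overlapping coverage
    between opposite-end reads is not guaranteed.
    """
    if n_clones < 1:
        raise SyntheticError("n_clones must be >= 1")
    if timepoint not in scenario.compositions:
        raise SyntheticError(f"timepoint {timepoint!r} absent from scenario")
    if read_direction not in ("5p", "3p", "mixed"):
        raise SyntheticError("read_direction must be 5p, 3p or mixed")
    tp_index = sorted(scenario.compositions).index(timepoint)
    rng = _rng(scenario.seed if seed is None else seed, 2, tp_index)
    comp = np.array(scenario.compositions[timepoint])
    counts = rng.multinomial(n_clones, comp)
    lo, hi = READ_LENGTH_RANGE
    clones = []
    clone_no = 0
    for taxon, count in zip(scenario.taxa, counts):
        gene = taxon.gene
        mutable = np.arange(20, len(gene) - 20)  # spare the primer regions
        for _ in range(count):
            clone_no += 1
            n_mut = rng.binomial(len(mutable), scenario.within_divergence)
            positions = rng.choice(mutable, size=n_mut, replace=False)
            seq = _mutate(rng, gene, positions)
            length = int(rng.integers(lo, min(hi, len(seq)) + 1))
            direction = read_direction
            if direction == "mixed":
                direction = "5p" if rng.integers(0, 2) == 0 else "3p"
            read = seq[:length] if direction == "5p" else seq[-length:]
            clones.append(
                MockClone(
                    clone_id=f"{scenario.label}_{timepoint}_c{clone_no:03d}",
                    taxon=taxon.name,
                    sequence=seq,
                    read=read,
                )
            )
    return MockCloneLibrary(f"{scenario.label}_{timepoint}", tuple(clones))


def simulate_degradation(
    scenario: CommunityScenario,
    timepoints: Sequence[float] = (0.0, 14.0, 39.0, 56.0),
) -> comm.DegradationSeries:
    """First-order propionate decay for the scenario's consortium.

    A failed batch keeps its initial concentration up to a small seeded
    multiplicative jitter (sigma 3%), mirroring measurement noise on a
    stalled fermenter.
    """
    p = scenario.decay
    if any(b <= a for a, b in zip(timepoints, list(timepoints)[1:])):
        raise SyntheticError("timepoints must be strictly increasing")
    rng = _rng(scenario.seed, 3)
    conc = []
    for t in timepoints:
        if p.failure:
            c = p.initial_mM * max(0.0, 1.0 + 0.03 * rng.standard_normal())
        else:
            c = p.initial_mM * exp(-p.rate_per_day * max(0.0, t - p.lag_days))
        conc.append(c)
    return comm.DegradationSeries(scenario.label, tuple(float(t) for t in timepoints), tuple(conc))


@dataclass
class RecoveryReport:
    """How faithfully the pipeline recovered a planted scenario."""

    n_taxa_true: int
    n_clusters_recovered: int
    membership_agreement: float
    tv_distance: dict[str, float]
    matrix: comm.CountMatrix

    @property
    def cluster_count_match(self) -> bool:
        return self.n_taxa_true == self.n_clusters_recovered


def run_round_trip(
    scenario: CommunityScenario,
    n_clones: int = 60,
    timepoints: Sequence[str] | None = None,
    identity_threshold: float = 97.0,
    coverage_threshold: float = 80.0,
) -> RecoveryReport:
    """Execute the whole pipeline on generated libraries and score it.

    Steps: verify each taxon gene amplifies with the packaged bacterial
    primers; ARDRA-group the clones of each library on their full insert
    sequences (two assays: HhaI and HinfI); cluster the 5'-end reads of
    the ARDRA group representatives; assign every clone to its
    representative's cluster; build the count matrix.

    Scoring maps each recovered cluster to its majority true taxon:
    membership agreement is the fraction of clones whose cluster maps to
    their own taxon, and the per-sample total-variation distance compares
    the recovered composition (over taxa) with the scenario's true
    composition vector.
    """
    primers = amp.load_primers()
    fwd, rev = primers["E5F"], primers["E1541r"]
    for taxon in scenario.taxa:
        products = amp.simulate_pcr(
            taxon.gene, fwd, rev, (500, 3000), source_id=taxon.name
        )
        if not products:
            raise SyntheticError(f"taxon {taxon.name} gene does not amplify")
    assays = amp.BACTERIAL_ASSAYS()
    tps = list(timepoints) if timepoints is not None else sorted(scenario.compositions)

    libraries = {tp: sample_clone_library(scenario, tp, n_clones) for tp in tps}
    clone_taxon: dict[str, str] = {}
    clone_group_rep: dict[str, str] = {}
    rep_records: list[clu.SequenceRecord] = []
    rep_reads: dict[str, str] = {}
    for tp, lib in libraries.items():
        profiles = [
            amp.ardra_profile(c.clone_id, c.sequence, assays) for c in lib.clones
        ]
        by_id = {c.clone_id: c for c in lib.clones}
        clone_taxon.update({c.clone_id: c.taxon for c in lib.clones})
        for group in amp.group_profiles(profiles):
            rep = group.representative
            rep_reads[rep] = by_id[rep].read
            for member in group.members:
                clone_group_rep[member] = rep
    rep_records = [clu.SequenceRecord(rid, read) for rid, read in rep_reads.items()]
    clusters = clu.cluster_sequences(
        rep_records, identity_threshold, coverage_threshold
    )
    rep_cluster = {
        member: cl.id for cl in clusters for member in cl.members
    }
    assignments = [
        comm.CloneAssignment(
            clone_id=cid,
            consortium=scenario.label,
            timepoint=tp,
            domain="bacteria",
            cluster_id=rep_cluster[clone_group_rep[cid]],
        )
        for tp, lib in libraries.items()
        for cid in (c.clone_id for c in lib.clones)
    ]
    totals = {(scenario.label, tp): n_clones for tp in tps}
    matrix = comm.build_count_matrix(assignments, totals)

    # Majority-taxon mapping of recovered clusters.
    votes: dict[str, dict[str, int]] = {}
    for a in assignments:
        votes.setdefault(a.cluster_id, {}).setdefault(clone_taxon[a.clone_id], 0)
        votes[a.cluster_id][clone_taxon[a.clone_id]] += 1
    majority = {
        cl: max(tally, key=lambda t: (tally[t], t)) for cl, tally in votes.items()
    }
    agree = sum(
        1 for a in assignments if majority[a.cluster_id] == clone_taxon[a.clone_id]
    )
    tv = {}
    taxon_names = [t.name for t in scenario.taxa]
    for tp in tps:
        recovered = dict.fromkeys(taxon_names, 0.0)
        for a in assignments:
            if a.timepoint == tp:
                recovered[majority[a.cluster_id]] += 1.0 / n_clones
        truth = dict(zip(taxon_names, scenario.compositions[tp]))
        tv[tp] = 0.5 * sum(abs(recovered[t] - truth[t]) for t in taxon_names)
    # Present = sampled at least once anywhere; absent taxa cannot be found.
    present = {t for t in clone_taxon.values()}
    return RecoveryReport(
        n_taxa_true=len(present),
        n_clusters_recovered=len(clusters),
        membership_agreement=agree / len(assignments),
        tv_distance=tv,
        matrix=matrix,
    )
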