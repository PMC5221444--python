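"""Community-level analytics over clone-count matrices.

Once clones are assigned to sequence clusters, everything downstream is
counting: a clusters x samples count matrix (samples are (consortium,
timepoint) pairs with a known library size), a dominance filter (present
in all three timepoints of a consortium, or at least 8% of one library),
guild summaries over the five functional groups of a propionate-degrading
community, per-cluster succession trends across t1-t3, and a
positive/negative verdict on each consortium's propionate degradation
series.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "GUILDS",
    "TIMEPOINTS",
    "CloneAssignment",
    "CountMatrix",
    "DegradationSeries",
    "CommunityError",
    "build_count_matrix",
    "dominant_clusters",
    "guild_summary",
    "GuildSummary",
    "succession_trend",
    "classify_degradation",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_guild_map",
]

#: The five functional guilds of a propionate-degrading community.
GUILDS = (
    "propionate-oxidizing",
    "acetate-oxidizing",
    "H2-oxidizing",
    "propionate-forming",
    "sugar-metabolizing",
)

UNASSIGNED = "unassigned"

#: Community sampling timepoints within a batch experiment.
TIMEPOINTS = ("t1", "t2", "t3")


class CommunityError(ValueError):
    """Raised for inconsistent community inputs."""


@dataclass(frozen=True)
class CloneAssignment:
    """One clone's membership: which sample it came from and which
    sequence cluster it belongs to."""

    clone_id: str
    consortium: str
    timepoint: str
    domain: str
    cluster_id: str

    def __post_init__(self) -> None:
        if self.domain not in ("bacteria", "archaea"):
            raise CommunityError(f"unknown domain {self.domain!r}")

    @property
    def sample(self) -> tuple[str, str]:
        return (self.consortium, self.timepoint)


@dataclass
class CountMatrix:
    """Clusters x samples clone counts with per-sample library totals.

    ``counts`` has cluster ids as rows and a (consortium, timepoint)
    MultiIndex as columns.  ``totals`` stores the number of clones
    sequenced per library; column sums may fall short of the totals when
    only dominant clusters are tabulated.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise CommunityError("negative clone counts")
        for sample in self.counts.columns:
            if sample not in self.totals.index:
                raise CommunityError(f"no library total for sample {sample}")
            if self.counts[sample].sum() > self.totals[sample]:
                raise CommunityError(
                    f"column sum exceeds library total for sample {sample}"
                )

    def consortium_block(self, consortium: str) -> pd.DataFrame:
        if consortium not in self.counts.columns.get_level_values(0):
            raise CommunityError(f"unknown consortium {consortium!r}")
        return self.counts[consortium]

    def proportions(self) -> pd.DataFrame:
        return self.counts / self.totals


@dataclass(frozen=True)
class DegradationSeries:
    """Propionate concentrations (mmol/L) over incubation days."""

    consortium: str
    timepoints: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints)
        cc = tuple(self.concentrations)
        if len(tp) != len(cc):
            raise CommunityError("timepoints and concentrations differ in length")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise CommunityError("timepoints must be strictly increasing")
        if any(c < 0 for c in cc):
            raise CommunityError("concentrations must be non-negative")
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "concentrations", cc)


def build_count_matrix(
    assignments: Sequence[CloneAssignment],
    totals: Mapping[tuple[str, str], int],
) -> CountMatrix:
    """Tally clone assignments into a clusters x samples count matrix.

    Every sample occurring in ``assignments`` must have a library total;
    clone ids must be unique.  Rows are ordered by total count descending,
    then by cluster label.
    """
    ids = [a.clone_id for a in assignments]
    if len(set(ids)) != len(ids):
        raise CommunityError("duplicate clone ids in assignments")
    for a in assignments:
        if a.sample not in totals:
            raise CommunityError(f"clone {a.clone_id!r} references sample {a.sample} "
                                 "missing from totals")
    columns = pd.MultiIndex.from_tuples(
        sorted(totals.keys()), names=["consortium", "timepoint"]
    )
    tally: dict[str, dict[tuple[str, str], int]] = {}
    for a in assignments:
        row = tally.setdefault(a.cluster_id, {})
        row[a.sample] = row.get(a.sample, 0) + 1
    counts = pd.DataFrame(
        [[tally[c].get(s, 0) for s in columns] for c in tally],
        index=list(tally),
        columns=columns,
        dtype=int,
    )
    if counts.empty:
        counts = pd.DataFrame(columns=columns, dtype=int)
    else:
        order = counts.sum(axis=1).sort_values(ascending=False, kind="stable")
        counts = counts.loc[
            sorted(counts.index, key=lambda c: (-order[c], c))
        ]
    ser = pd.Series({s: int(t) for s, t in totals.items()})
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["consortium", "timepoint"])
    return CountMatrix(counts, ser)


def dominant_clusters(
    matrix: CountMatrix,
    consortium: str,
    proportion_threshold: float = 0.08,
) -> set[str]:
    """Clusters that dominate one consortium's community.

    A cluster qualifies when its count is positive in all three
    timepoints, or when it reaches at least ``proportion_threshold`` of
    the sequenced library in at least one timepoint.
    """
    block = matrix.consortium_block(consortium)
    for tp in TIMEPOINTS:
        if tp not in block.columns:
            raise CommunityError(f"consortium {consortium!r} lacks timepoint {tp}")
        if matrix.totals[(consortium, tp)] <= 0:
            raise CommunityError(f"zero library total for ({consortium}, {tp})")
    dominant = set()
    for cluster in block.index:
        counts = [block.loc[cluster, tp] for tp in TIMEPOINTS]
        props = [
            c / matrix.totals[(consortium, tp)] for c, tp in zip(counts, TIMEPOINTS)
        ]
        if all(c > 0 for c in counts) or any(p >= proportion_threshold for p in props):
            dominant.add(cluster)
    return dominant


@dataclass
class GuildSummary:
    """Per-sample guild counts and proportions (of the sequenced library)."""

    counts: pd.DataFrame
    proportions: pd.DataFrame


def guild_summary(matrix: CountMatrix, guilds: Mapping[str, str]) -> GuildSummary:
    """Collapse a count matrix onto the five functional guilds.

    ``guilds`` maps cluster labels to guild names; clusters missing from
    the map are collected under ``unassigned``.  Proportions divide by the
    library totals, so guild proportions plus unassigned sum to at most 1
    (less when non-dominant clones were withheld from the matrix).
    """
    if not guilds:
        raise CommunityError("empty guild map")
    bad = {g for g in guilds.values() if g not in GUILDS}
    if bad:
        raise CommunityError(f"unknown guild name(s): {sorted(bad)}")
    rows = list(GUILDS) + [UNASSIGNED]
    counts = pd.DataFrame(0, index=rows, columns=matrix.counts.columns)
    for cluster in matrix.counts.index:
        guild = guilds.get(cluster, UNASSIGNED)
        counts.loc[guild] += matrix.counts.loc[cluster]
    proportions = counts / matrix.totals
    return GuildSummary(counts, proportions)


def _trend(p1: float, p2: float, p3: float) -> str:
    if (p1 < p2 <= p3) or (p1 <= p2 < p3):
        return "increasing"
    if (p1 > p2 >= p3) or (p1 >= p2 > p3):
        return "decreasing"
    return "none"


def succession_trend(matrix: CountMatrix, consortium: str) -> pd.DataFrame:
    """Per-cluster proportions at t1-t3 and a monotone trend call.

    A cluster is ``increasing`` when its library proportion rises with a
    strict increase in at least one step and no decrease (``decreasing``
    by the mirror rule); ties alone give ``none``.
    """
    block = matrix.consortium_block(consortium)
    for tp in TIMEPOINTS:
        if tp not in block.columns:
            raise CommunityError(f"consortium {consortium!r} lacks timepoint {tp}")
        if matrix.totals[(consortium, tp)] <= 0:
            raise CommunityError(f"zero library total for ({consortium}, {tp})")
    out = {}
    for cluster in block.index:
        props = [
            block.loc[cluster, tp] / matrix.totals[(consortium, tp)]
            for tp in TIMEPOINTS
        ]
        out[cluster] = (*props, _trend(*props))
    return pd.DataFrame.from_dict(
        out, orient="index", columns=["p1", "p2", "p3", "trend"]
    )


def classify_degradation(
    series: DegradationSeries, residual_fraction: float = 0.10
) -> str:
    """Call a consortium's propionate degradation positive or negative.

    ``positive`` when the final concentration is at most
    ``residual_fraction`` of the initial one; the batch failed otherwise.
    """
    if len(series.concentrations) < 2:
        raise CommunityError("need at least two concentration points")
    initial, final = series.concentrations[0], series.concentrations[-1]
    if initial == 0:
        raise CommunityError("initial propionate concentration is zero")
    return "positive" if final / initial <= residual_fraction else "negative"


# ---------------------------------------------------------------------------
# Packaged study fixtures
#
# Small TSV tables describing the four propionate-degrading consortia
# (Ap1a, G12, N12, Wp2a): degradation series, dominant bacterial clone
# counts per sample, archaeal clone counts at t2, and the taxon -> guild
# map.  Bacterial clone libraries held up to 60 clones; only dominant
# clusters are tabulated, so the nominal library size of 60 is stored as
# the per-sample total (column sums are lower bounds on clones screened).


def _read_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("synprop.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_table1() -> dict[str, DegradationSeries]:
    """Propionate degradation series for the four consortia."""
    df = _read_tsv("table1_degradation.tsv")
    out = {}
    for consortium, grp in df.groupby("consortium", sort=False):
        grp = grp.sort_values("day")
        out[consortium] = DegradationSeries(
            consortium,
            tuple(grp["day"].astype(float)),
            tuple(grp["propionate_mM"].astype(float)),
        )
    return out


def load_table2(nominal_total: int = 60) -> CountMatrix:
    """Dominant bacterial clone counts per consortium sample."""
    df = _read_tsv("table2_bacterial_clones.tsv")
    counts = df.pivot_table(
        index="taxon",
        columns=["consortium", "timepoint"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    ).astype(int)
    counts = counts.loc[df["taxon"].drop_duplicates().tolist()]
    totals = pd.Series(nominal_total, index=counts.columns)
    return CountMatrix(counts, totals)


def load_table3(nominal_total: int = 12) -> CountMatrix:
    """Archaeal clone counts at t2 for the four consortia."""
    df = _read_tsv("table3_archaeal_clones.tsv")
    counts = df.pivot_table(
        index="taxon",
        columns=["consortium", "timepoint"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    ).astype(int)
    counts = counts.loc[df["taxon"].drop_duplicates().tolist()]
    totals = pd.Series(nominal_total, index=counts.columns)
    return CountMatrix(counts, totals)


def load_guild_map() -> dict[str, str]:
    """Taxon label -> guild for the dominant bacterial clusters."""
    df = _read_tsv("guilds.tsv")
    return dict(zip(df["taxon"], df["guild"]))
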