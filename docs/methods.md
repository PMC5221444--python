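# Methods

This note documents the models, conventions and design choices behind
`synprop`, in the order of the pipeline.

## Free-energy model

Every reaction is a map from species names to signed rational
stoichiometric coefficients plus a standard-condition free energy
ΔG⁰′ (kJ per reaction as written). Evaluation is

ΔG′ = ΔG⁰′ + R·T·ln Q,  R = 8.314 J mol⁻¹ K⁻¹,

with the biochemical ("prime") standard state: solutes in mol L⁻¹
against 1 mol L⁻¹, gases in atm against 1 atm, water at activity 1, and
the proton activity divided by 10⁻⁷ so the proton term vanishes at pH 7.
Activity coefficients are 1 (dilute approximation) and ΔG⁰′ is **not**
temperature-corrected — no van 't Hoff/enthalpy adjustment — so
temperature enters only through RT·ln Q. These conventions, with
T = 310.15 K for the 37 °C reference conditions, reproduce the published
integer-kJ free-energy sweep to within ±1 kJ in every cell (asserted in
the acceptance tests before the constants were locked).

The packaged registry holds the five coupled reactions with
Thauer-compilation constants: propionate oxidation +76.1, hydrogenotrophic
methanogenesis −135.6, acetoclastic methanogenesis −31.0, syntrophic
acetate oxidation (SAO) +104.6 and autotrophic homoacetogenesis (AHA)
−104.6 kJ. Two registry identities are asserted at load: AHA is the exact
negation of SAO, and SAO + hydrogenotrophic methanogenesis equals
acetoclastic methanogenesis in both stoichiometry and ΔG⁰′
(104.6 − 135.6 = −31.0). Note the literature also prints −25.2 kJ for the
propionate-oxidation + 0.75·methanogenesis coculture; the registry
constants give −25.6, and the −56.6 kJ figure for the complete conversion
is exactly consistent with −25.6 − 31.0. We treat the table and the
complete-conversion figure as canonical and record the −25.2 as source
rounding.

Crossovers are solved in closed form: with all non-H₂ activities fixed,
ΔG′(pH₂) = a + ν·RT·ln pH₂ with ν the H₂ coefficient, so the root is
pH₂ = exp(−a/(ν·RT)). Root bracketing is retained only as a test oracle.
The syntrophic "hydrogen window" of a producer/consumer pair is the open
interval (consumer crossover, producer crossover); a lower bound at or
above the upper bound means no window. Table cells are displayed as
nearest-integer kJ with ties rounded away from zero.

Coefficients are `fractions.Fraction`s so linear combinations cancel
exactly; a fully cancelling combination yields a null reaction with empty
stoichiometry whose ΔG′ is its (possibly nonzero) combined ΔG⁰′.

## In-silico PCR and ARDRA

Primer-site scanning is IUPAC-compatibility matching (two codes match
when their base sets intersect) on both strands, with a strict 3′ anchor:
the primer's terminal base must match regardless of the mismatch
allowance (default 0), mimicking the polymerase extension requirement.
Amplicons pair each forward hit with the nearest downstream
reverse-complemented reverse hit within length bounds and include both
primer regions; coordinates are 0-based half-open on the top strand,
minus-strand products carry mirrored coordinates. Molecules are always
linear.

Restriction digestion takes the union of cut positions (site start + cut
offset) over the enzymes of one reaction, deduplicated; fragments are the
gaps between consecutive cuts and the ends and always sum to the input
length. The packaged enzyme registry uses standard catalogue sites —
HhaI GCG^C, HinfI G^ANTC, HaeIII GG^CC, SmaI CCC^GGG, XhoI C^TCGAG — all
reverse-complement palindromes (asserted at load), so top-strand scanning
finds every double-strand cut. One subtlety: for staggered cutters, the
top-strand fragment lengths of a sequence and of its reverse complement
differ at the two terminal fragments by the overhang (≤3 nt here), an
effect far below gel resolution; the test suite asserts this corrected
symmetry rather than exact equality.

Gel binning models a 2% agarose readout: fragments under the detection
limit (default 50 nt) are dropped, and adjacent fragments (sorted
descending) merge into one band when they differ by less than a relative
tolerance (default 0.05) of the larger length; a band is the rounded mean
of its members. Both knobs are exposed because no resolution criterion
accompanies the published protocol; 2% agarose cannot separate ~5% length
differences, which fixes the default. ARDRA groups are clones whose
binned patterns are identical across all assays (bacteria: HhaI and HinfI
separately; archaea: HaeIII, and SmaI+XhoI together), keyed by a
canonical serialization, in order of first appearance.

## Pairwise identity and clustering

Reads covering one end of a shared gene are compared by optimal global
alignment with free terminal gaps (match +2, mismatch −1, gap open −4,
extend −1, via Biopython's `PairwiseAligner`). Identity is matches over
alignment columns excluding terminal-gap columns; internal gap columns
count as mismatches. Coverage is the aligned span of the query over its
length. A consequence of free end gaps worth knowing: terminal mismatches
are trimmed rather than aligned (two zero-cost end gaps outscore a −1
column), so identity is computed over the trimmed core.

Clustering follows BLASTclust semantics: single linkage over the graph
with an edge wherever identity ≥ 97% and coverage ≥ 80% with *each*
record taken as the query (both-member coverage, the BLASTclust default —
this is what keeps a high-identity half-length fragment out of a
full-length cluster). Representatives are the longest member, ties to the
lexicographically smallest id; clusters are ordered by decreasing size.
Raising the identity threshold can only refine the partition.

Taxonomy assignment aligns the representative against a user-supplied
reference set (no live database queries): best identity wins, ties broken
by coverage then name; identity strictly above 97% yields a species-rank
call, anything at or below falls back to genus. The clustering threshold
itself is inclusive (≥ 97) while the species rule is strict (> 97),
mirroring how each criterion is conventionally stated. Two-direction read
sets (5′- and 3′-end reads) should be clustered per direction — opposite-
end reads of a ~1.5 kb gene need not overlap at 80% coverage; the
pipeline performs one pass over whichever read set is supplied. Chimera
screening is assumed to have happened upstream.

## Community analytics

The count matrix stores clusters × (consortium, timepoint) clone counts
together with per-library totals. Totals are kept separately from column
sums because published tables often list only dominant clusters; the
packaged fixtures use the nominal library size of 60 bacterial (12
archaeal) clones as the denominator, with column sums as lower bounds on
clones screened.

Dominance: a cluster dominates a consortium when its count is positive at
all three timepoints, or reaches at least 8% (inclusive) of one library.
Guild summaries collapse clusters onto the five functional guilds
(propionate-oxidizing, acetate-oxidizing, H₂-oxidizing,
propionate-forming, sugar-metabolizing) with unmapped clusters under
"unassigned", so guild counts plus unassigned equal the column sum.
Succession trends require a monotone proportion sequence with at least
one strict step (ties alone → "none"). Degradation verdicts call a series
positive when the final concentration is at most 10% of the initial one —
a configurable rule chosen because it reproduces all four packaged
verdicts, including the consortium that retains 4% residual propionate
(positive) and the stalled one at 92% (negative).

## Synthetic data

The generator plants an ancestor gene (resolved forward primer + random
core + reverse-complemented resolved reverse primer, 1500 nt by default)
and derives taxa by substituting disjoint random core position sets, so
realized pairwise divergences are exactly twice the per-taxon load —
targeted at 1.25× the requested floor, capped at 0.3, hence always inside
[floor, 0.3]. Primer sites are never mutated. Mutations are independent
uniform substitutions without indels, keeping divergence arithmetic exact
for tests.

Clone libraries draw taxa multinomially from a per-timepoint composition
(explicit or flat-Dirichlet), mutate each clone at the scenario's
within-cluster rate (default 1%, i.e. clone-to-clone ≈2%, comfortably
inside a 97% cluster), and cut a single-pass read of uniform random
length 747–1141 nt anchored at the 5′ end by default (3′ or mixed
optionally). Degradation curves follow
c(t) = c₀·exp(−k·max(0, t − lag)); the failure flag forces k = 0 with 3%
multiplicative jitter. All randomness flows from
`numpy.random.default_rng([seed, stream…])` with fixed per-operation
stream indices, so identical seeds give identical datasets.

The round-trip harness runs the full pipeline — amplifiability check,
ARDRA on each clone's full insert, clustering of the ARDRA group
representatives' 5′ reads, clone-to-cluster assignment, count matrix —
and scores recovery by mapping each cluster to its majority true taxon:
membership agreement (fraction of clones mapped to their own taxon) and
per-sample total-variation distance against the true composition.
Problem sizes used throughout the checked results: libraries of 60
clones, 3–5 taxa, 20 seeds for the statistical acceptance properties.

## What the synthetic tests do and do not show

The generator reproduces the *statistical* structure the analysis relies
on — planted divergence gaps, multinomial sampling noise, primer
conservation — but not real 16S biology: no secondary-structure or
conserved/variable-region architecture, no indels by default, no chimeras,
no quality decay along reads, and ARDRA patterns of mock genes are
random-sequence patterns rather than genuine restriction maps. Passing
round trips therefore demonstrate that the pipeline's logic is correct
and well-calibrated for its thresholds, not that those thresholds are
optimal for field data. Clone-level mutation can create or destroy
restriction sites, so ARDRA groups legitimately outnumber taxa (as in
real libraries); read-length spread can split one taxon's reads across
clusters under the strict both-member coverage gate, which leaves
composition recovery unaffected (majority mapping) but can raise the raw
cluster count above the planted taxon count.

## Numerical notes and limitations

* Exact rational stoichiometry; free energies in double precision.
* Crossovers assume all non-H₂ activities fixed; no speciation chemistry
  (CO₂/HCO₃⁻ equilibria), ionic-strength or Davies corrections, and no
  kinetic modelling — the hydrogen window is a purely thermodynamic
  statement.
* Alignment identity between co-optimal alignments is implementation-
  defined; tests pin it only where the optimum is unambiguous.
* The dominance and degradation thresholds are analysis conventions, not
  fitted parameters; both are exposed as function arguments.
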