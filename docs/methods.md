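# Methods

This note records the models, numerical choices, and design decisions
behind phagekit, and what the synthetic-data tests do and do not establish
about real data.

## Fragment ANI engine

### Model

ANI between two genomes is defined operationally, as the fragment-mapping
tools define it: cut the query into non-overlapping fragments of length
*L*, place each fragment on the reference, and average the identities of
the fragments that place well. This deliberately measures identity only
over the alignable fraction of the genomes; the complementary signal —
how much of the query aligns at all — is reported separately as coverage.
The two numbers must be read together: a pair can be near-identical over
half a genome (high ANI, low coverage), which is a different biological
situation from uniform 95% identity.

### Fragmentation rule

Fragments start at position 1 and tile the genome; a trailing remainder
shorter than L/2 is dropped, otherwise kept as a short final fragment, and
a genome shorter than L/2 cannot be fragmented (error). The L/2 rule is
this package's choice: keeping tiny remainders would let a 200 bp tail
carry the same weight in the ANI mean as a full fragment.

### Placement and identity

Candidate placements are found by exact k-mer seeding (k = 16 by default,
both strands indexed through the fragment's reverse complement) with seed
diagonals clustered into candidate regions; each candidate window (plus a
10%-of-L margin on each side) is aligned semi-globally — whole fragment,
free-ended reference window — by bit-parallel edit-distance alignment
(edlib). Fragment identity is

    identity = 1 − editDistance / L.

This normalisation was chosen over matches-per-alignment-column because the
latter is not a function of the optimal score: co-optimal minimum-distance
alignments can have different column counts and hence different
matches/columns values, which makes exact validation against an independent
dynamic-programming oracle impossible. The edit-distance form is
deterministic given the optimal distance, coincides with matches/columns
whenever the optimal alignment is substitution-only (the regime that
dominates within-species comparisons), and is validated to 10⁻⁹ against a
full, unseeded, unbanded DP oracle in the test suite. Ties between
equal-identity placements resolve to the forward strand, then the lowest
reference offset, so output is deterministic.

A fragment counts as aligned at identity ≥ `min_identity` (default 0.80,
matching the convention of masking pairs below 80% ANI in displays). With
semi-global placement the whole fragment is inside the alignment by
construction.

### Parameters

| parameter | default | rationale |
|---|---|---|
| `fragment_length` | 3,000 bp | the default of the fragment-ANI tool family; 42–63 kb phage genomes yield only ~14–21 fragments, so coverage is quantized in ~5–7% steps — the knob exists for exactly that reason |
| `min_identity` | 0.80 | aligned-fragment floor; mirrors the <80% display mask |
| `kmer_size` | 16 | long enough that random 3 kb × 60 kb comparisons share ~0.03 spurious seeds, short enough to survive 5% divergence |
| `seed_stride` | 8 | only every 8th fragment k-mer is looked up; candidate regions need a handful of seeds, not all ~3,000 |
| `max_candidates` | 5 | regions aligned per strand, ranked by seed support |
| `window_margin` | 0.10 | window slack for indels; the accuracy/speed knob that replaces an explicit alignment band |

Known limitation: a fragment that partially overlaps a large foreign
insertion can align just above the identity floor (e.g. at 0.82) and pull
the pair's ANI down by up to (1 − 0.8)/n_fragments — roughly 1–1.5
percentage points for phage-sized genomes. This threshold sensitivity is
intrinsic to fragment ANI, not to this implementation; it matters when a
pair sits within ~2 points of a decision threshold.

### Symmetrization

Directed ANIs of a pair are averaged when both are defined; if only one
direction has aligned fragments, the defined value is used; if neither,
the pair's ANI is undefined (NaN) and treated as no-edge downstream.
Coverage is always the mean of the two directed coverages. Diagonals are
100 by construction.

## Species and genomovar delineation

Thresholds are inclusive: ANI ≥ 95% same species, ≥ 99.5% same genomovar,
and an edge additionally requires coverage ≥ `coverage_floor` (default
50%, a permissive floor — published species-mates appear at 84–95%
coverage and no stricter floor is standardized). Single linkage (connected
components) is the default because threshold-exceedance grouping without a
stated linkage is weakest-assumption single linkage; it can chain A–B–C
into one species when ani(A,C) < 95, which is scientifically defensible
(species as a connected similarity cluster) but worth knowing. Complete
linkage (greedy maximal cliques in deterministic id order) is available
for the conservative reading. Output order is deterministic: groups sorted
by smallest member id.

## Window identity tracks

Windows are defined on the reference's *ungapped* coordinates (runs of 50
reference bases), not on alignment columns, so track x-axes match genome
maps. Per window and query:

* identity = columns where the query equals the reference (both non-gap) /
  reference bases in the window — query gap columns count as mismatches in
  the default mode (`query_gap_mode="mismatch"`); the `"exclude"` mode
  drops them from the denominator instead, since an aligner's placement of
  a deletion is a modelling choice the track should be able to ignore;
* present = query non-gap fraction ≥ 0.5 — short gaps depress identity,
  long gaps flip the presence flag (the thick/thin line distinction);
  identity is NaN where not present.

The consensus track is the per-window mean identity over queries with the
window present. The MSA itself is an input: the computation is defined on
any aligned FASTA and deliberately does not bundle an aligner.

## Feature calls

**Reorientation.** Genomes are treated as circularly permutable — justified
by the headful-packaging prediction for these phages — and rotated so the
single terL annotation starts at position 1 on the forward strand
(reverse-complementing first if terL is on the minus strand). Annotations
are remapped; a gene spanning the new origin is split into two part
records. A strict `mode="linear"` refuses to rotate. The operation is
idempotent and length-preserving (property-tested).

**Packaging.** A closed lookup table maps terL Pfam families to packaging
mechanisms; it ships with Terminase_6 (T7-like) and Terminase_3 (Sf6-like),
both → headful. Unknown labels report `unknown` rather than guessing.

**polA position 762.** The candidate protein is aligned globally (BLOSUM62,
gap open −11, extend −1) to a packaged numbering reference, and the residue
in the column aligned to reference position 762 is read out; the speed-class
map {F, Y → fast_processive; L → slow_accurate} is closed. Position 762 is
indexed on the full-length protein, counting the initiator methionine.
Homology is gated at 20% identity computed over *all* alignment columns
(gaps included): identity over matched columns only is inflated to ~30%
even between unrelated proteins, because affine-gap alignment cherry-picks
matching stretches. The packaged reference
(`data/synthetic_pola_reference.fasta`) is a constructed synthetic stand-in
with the real enzyme's length (928 aa) and phenylalanine at position 762;
the read-out algorithm is independent of the reference's composition, but
users analysing real polA genes should substitute the E. coli PolA
sequence (UniProt P00582) via the `reference` argument for meaningful
homology gating.

**Gene-content clustering.** Greedy centroid clustering: proteins sorted by
descending length (ties by genome and gene id), each joining the first
cluster whose founder it matches at ≥ 50% identity over aligned columns
with the aligned columns covering ≥ 80% of the shorter sequence (global
edit-distance alignment). These are conventional orthology heuristics; the
report is explicitly not a reproduction of graph-based pangenome pipelines
(MCL and kin), whose cluster counts it will not match in general. Core =
clusters touching every genome; unique = clusters confined to one genome.

## Morphometrics and titers

Per-particle ellipsoid volumes are computed first and then averaged;
group mean volume therefore exceeds the volume of the group's mean
dimensions (Jensen's inequality, asserted as a property test) — the reason
reported mean volumes look "too big" relative to mean dimensions. Welch's
t is computed directly with Welch–Satterthwaite df (cross-checked against
scipy); no multiple-testing correction is applied. Titer estimation
requires the counting geometry (square area and effective filter area in
mm², filtered volume in mL) explicitly — there are no defaults, forcing
provenance — and is linear in mean count and dilution, inverse-linear in
volume.

## Geographic analysis

Haversine great-circle distance on a spherical Earth (R = 6,371.0 km):
at the ~70 km scale of a regional soil survey the difference from a
geodesic ellipsoid is below 0.5%, and the method is dependency-free. The
Mantel statistic is the Pearson correlation (Spearman selectable) of
upper-triangle entries; the null jointly permutes rows and columns of one
matrix; the two-sided p is (1 + #{|r*| ≥ |r|})/(1 + n_permutations) with a
mandatory seed (default 9,999 permutations). Subset runs report skips —
n < 3, an undefined ANI pair (unalignable outgroup), zero-variance
distances (a near-clonal species) — as data rather than raising, because
those degeneracies are expected outcomes in real cohorts.

## Synthetic cohort generator

Each cluster evolves on a star phylogeny: one ancestor drawn i.i.d. with
P(G or C) = gc_target, members derived by independent per-site substitution
(uniform over the three alternatives), giving expected sibling identity
(1−p₁)(1−p₂) + p₁p₂/3 — recorded in the truth object and recovered by the
parameter-recovery tests. Indels initiate per intergenic-spacer site with
geometric lengths, and accessory genes insert between core genes, so
planted annotation coordinates remain valid. Substitutions are GC-agnostic;
GC is enforced at the ancestor only (drift at p ≤ 0.05 is negligible).
Morphometrics are truncated-positive Gaussians; grid counts are Poisson
with the mean implied by the true titer and geometry, making the titer
estimator unbiased by construction.

The 16-genome preset (`preset_cohort_config`) plants: a 12-member cluster
(GC 0.67, ~63 kb) with eight substitution-only lineages at expected
pairwise identity ~99.8% (one genomovar) and four looser lineages (~98.5%,
with indels and a private accessory gene each); a 3-member cluster (GC
0.44, ~57 kb) at ~97% — one species, no genomovars; and an independent
outgroup (GC 0.59, ~42 kb). Near-threshold lineages carry no accessory
islands: a fragment partially overlapping an island aligns just above the
identity floor and drags pair ANI by up to ~1.5 points, which would make
the planted structure unrecoverable by *any* fragment-ANI method at the
95% threshold — the island machinery is instead exercised by the loose
lineages, whose identities have wide margins to both thresholds. Isolation
sites (ten, spanning ~70 km) are assigned uniformly at random per member,
independent of divergence, so the preset plants no geography–divergence
association; the Mantel power suite plants distance decay separately, at
the distance-matrix level (divergence = 0.5% + 0.05%/km + Gaussian noise,
sd 0.25), because evolving 100 full genome cohorts for a power curve would
be computation without information gain.

### What passing tests show — and don't

The generator's star phylogeny has no recombination, mosaicism, codon
structure, or GC drift, and its accessory genes are random sequence rather
than real gene families. Tests against it certify the *computational*
contracts — identity estimates match analytic expectations, planted
partitions are recovered, estimators are calibrated and unbiased — not
that real phage cohorts satisfy the model. In particular, real phage
mosaicism can place a pair high on ANI and low on coverage in ways the
star model never generates; the ANI/coverage pairing exists precisely to
surface that case.

### Problem sizes

Statistical suites run at sizes chosen for tight feedback loops: the
200-seed partition-recovery suite uses the preset at scale 0.2 (≈12 kb
ancestors, 1 kb fragments — thresholds and structure unchanged), the
analytic-identity checks use 50 kb substitution-only pairs, Mantel
calibration uses 500 null replicates (199 permutations) and 100 power
replicates (999 permutations), and the acceptance script runs the preset
at full size (42–63 kb genomes, 3 kb fragments) once. Scale changes genome
length only, never the planted divergences or thresholds.

## Known limitations

* ANI values are not numerically identical to any specific external tool's
  output; agreement is at threshold level (species calls), which is what
  the delineation consumes.
* Coverage quantization at ~14–21 fragments per genome means coverage
  moves in ~5–7% steps; interpret small coverage differences accordingly.
* The greedy protein clustering is order-stable but centroid-based;
  borderline pairs near the identity threshold can split differently than
  a graph-clustering pipeline would.
* The packaged polA numbering reference is synthetic; residue read-out
  relative to it is exact, but homology screening of real proteins needs
  the real reference sequence supplied by the user.
* Haversine assumes a spherical Earth; at continental scales use a
  geodesic library if sub-0.5% distance accuracy matters.
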