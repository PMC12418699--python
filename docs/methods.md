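# Methods

This note documents the models, parameter choices and numerical decisions
behind `cenarch`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Substitution model and the molecular clock

The simulator and the dating module share one model: after insertion, each
LTR copy accumulates substitutions independently at rate r per site per
year (default 1.3 × 10⁻⁸, the standard grass neutral rate). Per site the
number of substitution events is Poisson with mean r·t; each event is a
transition with probability κ/(κ+2) and otherwise one of the two
transversions uniformly. κ defaults to 2, which makes transition and
transversion events equally likely per event; the published wheat
transition:transversion ratio for LTR divergence is not known, so κ is
exposed as a free parameter and nothing downstream depends on it — the
Kimura two-parameter (K2P) correction estimates P and Q separately and is
consistent for any κ. No indels are simulated by default; an optional
truncation flag produces elements that must *not* be detected, for
negative controls.

Expected LTR-pair divergence after t years is 2rt, so the K2P estimate
K ≈ 2rt and age = K/(2r) recovers t. The acceptance benchmark plants 50
elements with 1.5-kb LTRs at each of 0.2/0.5/1.0/2.0 Ma and requires the
regression slope of estimated on true age to sit within 1 ± 0.1; typical
runs give slopes of 0.99–1.04.

Dating numerics:

- Global alignment with match +2, mismatch −2, linear gap −3 (the same
  scores the detector uses). Gaps carry an extra 10⁻⁴ penalty so
  alignments that tie on the integer scores resolve toward substitution
  columns: a transposed base pair scores the same mismatched as gapped,
  and letting the aligner choose gaps silently deflates divergence (we
  measured a 7 % downward bias in the clock slope before this tie-break).
- Gap columns and ambiguous (non-ACGT) columns are excluded from the
  column count, distmat-style.
- K2P requires 1−2P−Q > 0 and 1−2Q > 0; outside that domain the element
  is flagged `saturated` and retained with `valid=False` and no numeric
  age. K is reported to 4 decimals, ages to 2 decimals (Ma). Incipient
  means K exactly 0 after exclusions.

## CENH3 enrichment and delimitation

Coverage is simulated and processed at bin level (10 kb by default for
chromosome-scale work): Input bins are Poisson(depth), ChIP bins are
Poisson(depth × fold) inside the centromere. The ratio track is
log2((ChIP+ε)/(Input+ε)) with ε = 0.5 after counts-per-million scaling.
Under CPM, an enriched domain spanning fraction f of the chromosome
depresses the whole track by log2(1+(fold−1)·f); for real Mb-scale
centromeres on 500–800 Mb chromosomes this is negligible, and the
delimitation benchmark therefore uses a realistic fraction (2 Mb on a
200-Mb chromosome), where the centromeric mean sits at 2.0 ± 0.1 for
4-fold enrichment. `normalize=False` is available when tracks are already
library-matched.

Delimitation takes maximal runs of bins ≥ 1.0 (log2 units), merges runs
separated by < 500 kb, drops merged runs < 500 kb, and marks the longest
surviving interval as the primary call. These defaults reproduce
contiguous Mb-scale domains of the kind the published wheat table reports;
all are exposed in `EnrichmentParams`. Internally all coordinates are
0-based half-open nt; Mb summaries round half-up to one decimal (the
published table's dialect — its 45.2/7 → 6.5 requires half-up).

## Structural flLTR-RT detection

Constraints follow the established structural definition: LTR length
100–2000 nt, start-to-start spacing 3000–25 000 nt, pair identity ≥ 0.85,
TSD 4–20 bp, TG…CA termini with ≤ 1 mismatch, boundary vicinity ± 60 nt,
seeds of 30 exact matching nt, x-drop 5 at match +2 / mismatch −2.
"Distance" is measured start-of-5′LTR to start-of-3′LTR.

The detector is seed-and-extend on exact 30-mer matches, with an
*ungapped* x-drop extension: the simulator is indel-free by design, gapped
divergence is handled at the dating stage, and an ungapped extension keeps
the diagonal (hence the LTR-length bookkeeping) exact. The indel score is
retained in `DetectorParams` for completeness. Uniform-ACGT background
makes chance 30-mer pairs vanishingly rare, which is why detection
precision can be meaningfully required to be 1.0 on synthetic fixtures.

Three behaviours were added after the plain textbook scheme failed on
realistic simulations:

- **Fragment chaining.** With xdrop 5, three consecutive mismatches stop
  the extension; at 5 % LTR divergence (~2 Ma) this happens about once
  per 2 kb of extension, splitting one LTR into fragments. Extension
  fragments on the same diagonal are merged whenever the merged stretch
  still meets the identity threshold.
- **Tandem mask.** A satellite array matches itself at every multiple of
  its unit length, and such self-matches satisfy every LTR-pair
  constraint — including, because the array is periodic, chance TSD and
  motif evidence. K-mers recurring with two or more consecutive gaps
  shorter than the minimum pairing distance (i.e. ≥ 3 copies at short
  period) mark a tandem mask, and candidates mostly inside it are
  dropped. Requiring ≥ 3 copies matters: two clustered elements of one
  family can legitimately place LTR copies < 3 kb apart, but their k-mer
  occurrence chains alternate short and long gaps.
- **Evidence model.** The TG…CA motif is checked on the termini of both
  LTR copies (8 positions tied through the repeat diagonal), since both
  copies of a genuine element carry the motif. Joint TSD+motif evidence
  is trusted anywhere within ±60 nt of the provisional boundaries, scored
  by tsd_length − shift (invariant along a true TSD, penalising distant
  chance repeats), with ties to the longer TSD. Motif-only evidence is
  trusted only within ±3 nt of the extension boundary, and a TSD alone
  must be ≥ 6 bp there: over a 121 × 121 placement search an unsupported
  exact 4-mer repeat is expected ~50 times by chance alone.

Overlap resolution keeps, within any mutually overlapping set, the element
with the strongest evidence tier (TSD+motif > motif > TSD > none), then
highest LTR similarity, then longer span, then leftmost. Evidence
outranks similarity because a chance pairing between the LTRs of two
neighbouring same-family elements shows genuine TG…CA termini and high
identity but never a TSD, and similarity-first ranking can let it displace
both real elements. By default elements lacking both TSD and motif are
discarded (`require_evidence`), playing the role of the integration filter
in the original multi-tool pipelines.

An independent check lives in `cenarch.bruteforce`: an exhaustive
diagonal scan (no seeding, no scoring, no x-drop) that reports every
window of ≥ min_ltr nt at ≥ 85 % identity over every admissible spacing;
on ≤ 20-kb windows the detector must find exactly the loci the scan finds.

## Classification and trees

Best-hit assignment computes global-alignment identity (edlib, gaps count
against) between the element and each library consensus; families below
`min_identity` = 0.80 report "other". The superfamily comes from the
assigned family's label — domain-based superfamily inference is out of
scope.

The tree is neighbor joining on K2P distances (pairwise global
alignments), implemented natively: Q-criterion with lexicographic
tie-breaks for determinism, negative branch lengths clamped to zero and
flagged, 2- and 3-taxon cases closed-form. Distance-based NJ replaces a
maximum-likelihood tree deliberately: downstream analysis consumes clade
membership, not branch support, and NJ's additive-matrix exactness (path
lengths reproduce an additive input to < 10⁻⁹) gives a sharp correctness
criterion, verified against brute-force least-squares topology choice on
quartets. Saturated pairs enter the distance matrix at 1.1 × the largest
finite distance, flagged. K2P matrices need not satisfy the triangle
inequality; nothing assumes it. Bootstrap is omitted.

## Comparative statistics

- **Dot plots** compare non-overlapping windows (500 bp for genome-scale
  comparisons, 300 bp for finer views) in both orientations using banded
  global alignment with band 2 × (1 − min_identity) × window.
- **Satellite monomers** are consecutive unit-length slices (trailing
  remainder dropped but counted); identity is global-alignment identity.
- **Age distributions** use Gaussian KDE with Silverman bandwidth,
  renormalised to integrate to 1 over the evaluation grid; degenerate
  cohorts (n < 2 or zero variance) are represented by a narrow Gaussian at
  the point mass. Medians/quartiles are computed on the raw ages.
- **Mann–Whitney U** uses midranks for ties; exact p by full enumeration
  of all C(n, n_x) assignments when n ≤ 12, otherwise a normal
  approximation with tie-corrected variance and continuity correction.
  Two-sided exact p is 2 × min(P≤, P≥) capped at 1. All-identical data
  returns p = 1.
- **Region partitions** label every base of a domain by how many
  ancestral accessions' enriched sets cover it (one / some / all), by
  derived-only coverage, or neither; ancestral coverage takes precedence
  over derived where both apply, and with a single ancestral set full
  coverage classes as "all". Contiguous same-class runs tile the domain
  exactly. The conventional numbering (1 = ancestral-one, 2 =
  derived-only, 3 = ancestral-some, 4 = neither, 5 = ancestral-all) is
  emitted as a map because the published numbering is positional per
  locus. Elements are assigned to segments by midpoint.
- **Copy tables** count elements per family per centromere call by
  midpoint; superfamily percentages round half-up to one decimal over the
  sum of supplied counts.

## Synthetic data: what it shows and what it does not

The generator emulates the statistical structure the analysis assumes:
i.i.d. uniform ACGT background, elements planted with TSDs and exact
TG…CA termini, independent post-insertion LTR divergence, bin-level
Poisson coverage with a single rectangular enrichment domain, and a
perfect tandem satellite array. A fixed seed makes every output
byte-identical across runs.

Real centromeres violate most of these simplifications: nested and
truncated insertions, indels, non-uniform base composition, mappability
artefacts in coverage, heterogeneous satellite higher-order structure.
Passing the synthetic benchmarks therefore demonstrates the correctness of
the implemented procedures under their own assumptions — boundary
bookkeeping, clock calibration, statistical exactness — not detector
performance on a real wheat assembly. The published real-data quantities
that depend on the full assembly and deposited ChIP data (per-centromere
element counts, the 1.20/0.23 Ma region medians, the R² = 0.91 replicate
correlation) are reproduced in *procedure* only, as property-level analogs
on synthetic cohorts.

Benchmark problem sizes were chosen to exercise every code path at
desk scale: a 1-Mb study chromosome with 20 elements for the worked
example, ~200-kb fixtures with 10 elements + 5 decoys for detection,
50 elements per age point for clock recovery, and n = 30 cohorts for the
region contrast.

## Interface choices

The package is organised as an analysis project: the library under
`src/cenarch` holds every computation; the numbered scripts under
`analysis/` are thin narrative drivers and, together with the library
functions, are the package's interface (no separate console entry point).
File formats are FASTA, BED/bedGraph (0-based half-open), GFF3 (1-based
inclusive, conversion at the format boundary only), Newick and TSV; every
writer's output passes its own reader's validation, and the pipeline
echoes its full configuration to YAML so any output is traceable to
parameters.
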