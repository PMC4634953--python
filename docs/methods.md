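# Methods

This note documents the models, conventions and numerical choices behind
`paleocollagen`, and what its synthetic benchmarks do and do not show about
real palaeoproteomic data.

## Digestion and mass arithmetic

Trypsin/P cleaves after every K and R, including before proline; the
C-terminal fragment is emitted even without a trailing K/R, and peptides
with up to a configurable number of missed cleavages are enumerated with
0-based half-open coordinates into the parent chain. Masses are monoisotopic
residue sums plus one water (18.0105646 Da); m/z assumes proton adducts
(1.007276 Da per charge). Modification deltas are kept at full precision —
carbamidomethyl-C 57.021464, K/P(/M) oxidation 15.994915, N/Q deamidation
0.984016 Da — because the conventionally printed 2-dp values accumulate
error over long peptides. Methionine oxidation is isobaric with collagen
hydroxylation; whether M counts as an oxidation target is a flag
(`oxidize_met`), off by default since hydroxyproline/hydroxylysine dominate
in collagen. Non-standard residue codes (U, B, Z, ...) are rejected with the
offending position rather than skipped: malformed input should fail fast.

## Target–decoy filtering

The per-analysis false discovery rate is the simplest decoy estimator,
100·(reported decoys)/(reported targets). The retention rule is the
*highest false positive score* (HFPS): keep target matches with score
**strictly greater** than the maximum reported decoy score of that same
analysis. Strict inequality matters: by construction no retained match
scores at or below the best known false positive. For extinct taxa sequenced
from duplicate specimens, only matches replicated in both specimens are
used; the replication key is (stripped peptide sequence, chain, reference
start). Modification state is deliberately excluded from the key —
diagenetic modifications vary between specimens, and requiring identical
modification state would discard genuinely replicated evidence
(`include_position=False` relaxes the key to sequence+chain). Two "replicate"
lists with the same specimen id are rejected.

## Consensus conventions

Peptides are placed at their reference coordinates; sites covered by no
peptide are X, and uncovered sites falling in reference-alignment gap
columns may be rewritten ? (an indel is expected there, so absence is
uninformative). Conflicting residue calls at a site are resolved by the
largest summed PSM score; an exact tie is called X and logged — an automated
deterministic rule standing in for what is traditionally a manual editing
decision. Because the mass-spectrometric workflow cannot distinguish leucine
from isoleucine, each alignment column containing both letters has its
proteomics-derived I/L calls rewritten to the more abundant of the two
across all sequences in the column; database-derived references are never
altered, and an exact tie keeps the observed letter. The two collagen chains
are concatenated through a single fixed R linker (1056 + 1 + 1041 = 2098
columns with the default chain lengths). Pairwise variation counts consider
only columns where both sequences carry a determined residue (not X/?/-);
the replicate-confirmed count additionally requires both specimens of the
fossil taxon to agree.

## MALDI fingerprint statistic

Peak lists are centroided (m/z, intensity) pairs inside the instrument
window (default 700–3700). The statistic takes each spectrum's `n` most
intense peaks (default 100; intensity ties break toward lower m/z) and
counts a one-to-one matching within a tolerance, default ±0.2 Da — a
conventional externally calibrated peptide-mass-fingerprint window; a ppm
mode is available. Matching is greedy by ascending m/z distance, which
prevents one peak absorbing several partners and makes the count symmetric.
Greedy maximal matching can fall below the true maximum matching in dense
ambiguous regions (never below half of it); the test suite bounds it against
a brute-force maximum-matching oracle. The diagonal of the pairwise matrix
is min(n, peaks available).

## Substitution model and likelihood

The engine implements the JTT empirical amino-acid model with the published
exchangeabilities and stationary frequencies (a `frequencies=` argument
gives a +F variant; the default is the model's own frequencies). The rate
matrix Q = S·diag(π) is forced to zero row sums and scaled so the mean rate
at stationarity is one; branch lengths are expected substitutions per site.
Transition matrices come from one symmetric eigendecomposition of
diag(√π)·Q·diag(1/√π) (real spectrum for any reversible Q), then
P(t) = exp(Qt·r) per rate category.

Rate heterogeneity is +I+G: proportion `p_inv` of invariant sites plus a
k=4 category discrete gamma with shape α. Discretisation uses
equal-probability bins with the **conditional mean** of each bin as the
category rate (mean-of-bin, computed in closed form from regularised
incomplete gamma functions, renormalised to mean one exactly); median-of-bin
differs numerically and is not offered. Gamma rates are divided by
(1 − p_inv) so the expected rate over the full mixture stays one — the
convention PhyML-family programs use.

Likelihood is Felsenstein pruning over compressed site patterns. X, ?, -
and any non-standard letter are fully missing: their conditional likelihood
vector is all ones, so an all-missing column contributes exactly zero log
likelihood. Per-pattern rescaling keeps partials in floating range on larger
trees. The invariant-sites component of a pattern is π of the shared
observed state when all observed characters agree (1 when none are
observed), else zero.

Agreement with two independent implementations is tested: exhaustive
enumeration over all internal-node state assignments (tiny trees), and R
phangorn's `pml` under JTT+G and JTT+I+G with missing data (both ≈ 1e-10).

## Optimisation and search

Branch lengths are optimised one edge at a time with bounded Brent
(bounds [1e-8, 20], tolerance 1e-6) against cached partial likelihoods
above and below the edge, so one evaluation costs O(patterns·400) rather
than a tree traversal; sweeps repeat until the gain drops below 1e-4, and a
proposed length is only adopted if it does not lower the likelihood, so the
log likelihood is non-decreasing.

α and p_inv are fitted **jointly** by Nelder–Mead over (log α, p_inv),
clipped to [0.05, 20] × [0, 0.8]. The two parameters are strongly
correlated — a small α puts mass at near-zero rates that mimics invariant
sites — leaving a narrow curved likelihood ridge on which
one-parameter-at-a-time updates stall far from the optimum; on 5000-site
simulations coordinate descent plateaued at clearly sub-optimal points the
simplex walks past. Model fitting alternates with branch-length sweeps
until the joint gain is below 0.01 log units.

Topology search is nearest-neighbour interchange from a neighbour-joining
start tree built on p-distances with pairwise deletion of missing sites
(scikit-bio's NJ; negative NJ branch lengths are floored). Both NNI
alternatives at every internal edge are scored with two loose-tolerance
branch sweeps; the best strictly improving swap is applied and the tree
fully re-optimised, to a local optimum. The procedure is deterministic given
its inputs. On easy five-taxon data the NNI optimum provably equals the
global optimum over all 15 topologies (tested by enumeration).

Bootstrap support resamples site patterns multinomially (equivalent to
resampling sites with replacement), reruns NJ+NNI per replicate with loose
tolerances (replicates only contribute a topology), and maps split
frequencies in percent onto the full-data ML tree. The default is 100
replicates — enough to read support at desk scale; production analyses
conventionally use thousands, which is a parameter, not a code change.
Rooting places the root at the midpoint of the outgroup's pendant edge and
changes no unrooted quantity (pulley principle; tested).

## Synthetic data generator

The generator emulates a two-chain collagen study: a Yule tree (branch
lengths rescaled to a mean of 0.05 substitutions/site — protein-level
divergence on a mammal-wide timescale), sequences evolved under the same
discrete +I+G mixture the inference assumes, per-site category assignments
drawn once. The chain-joining linker column is fixed to R in every taxon:
it is an alignment convention, not an evolving site. The last taxa play the
extinct role: their true sequences are withheld and replaced by
replicate-specimen PSM tables obtained by digesting the truth (≤2 missed
cleavages), admitting peptides in random order until union coverage reaches
a target drawn from U(0.56, 0.77), drawing binomial hydroxylation (rate
0.3/eligible residue — collagen prolines are heavily hydroxylated) and
deamidation (0.1), Normal target scores (μ=60, σ=15) and reversed-peptide
decoys with Normal scores (μ=15, σ=6). As with a real search engine, only
matches above a significance score (25) are reported, plus always the best
decoy, which defines the HFPS; reported FDRs then land at a few percent.
MALDI fingerprints are the singly protonated tryptic masses inside 700–3700
with log-normal intensities plus uniform noise peaks. All randomness flows
from one master seed; identical configurations give byte-identical outputs.

**Identifiability floor.** Internal branches of simulated trees are floored
at 0.01 expected substitutions/site (≈20 expected changes over 2098 sites).
Unfloored Yule draws occasionally contain internal edges carrying under ten
expected changes; there the maximum-likelihood tree *genuinely* differs from
the generating topology (verified by comparing likelihoods, and by NNI
started from the truth walking away from it), so a topology-recovery
benchmark without the floor measures statistical unidentifiability rather
than method quality. Short-chain test fixtures raise the floor
proportionally to keep the per-edge expected change count comparable.

What the generator does **not** model: correlated peptide detectability
between specimens (real replicate specimens share ionisation biases, so
real replicate intersections retain considerably more coverage than two
independently sampled specimens do here), collagen's Gly-X-Y positional
composition (JTT has no positional model, and the inference engine is the
benchmark target), fragment-ion spectra, chromatography, isotope envelopes,
and deamidation as an age signal. Passing the synthetic benchmarks
therefore demonstrates correctness of the algorithms under the assumed
generative model, not robustness to every bias of real ancient-protein
data.

## Problem sizes in the test and acceptance runs

The suite exercises the pipeline at the study's native scale where the
claim depends on it: 2098-site alignments for topology recovery (20
replicates, 8 taxa, two taxa masked to 60% coverage; 100 bootstrap
replicates on one of them), 5000 sites for (α, p_inv) recovery on a fixed
8-taxon tree whose branch lengths span 0.02–0.5 (rate-parameter
identifiability requires branch-length spread), 1000 random ≤5-taxon
instances for the enumeration oracle, and 50 replicates × 6 substitution
levels for the fingerprint statistic. Unit tests use shorter chains
(200–560 columns) to stay fast; `scripts/acceptance.py` records the problem
size it used alongside every number.

## Known limitations

- Likelihood scaling is per-pattern, adequate to a few hundred taxa, but
  the NNI candidate loop re-optimises branch lengths per candidate and is
  intended for dozens of taxa, not thousands.
- The (α, p_inv) ridge is intrinsically flat on shallow ultrametric trees;
  fits on such data are honest maximum-likelihood values but can sit far
  from the generating parameters (the tree, not the optimiser, is the
  limitation).
- The consensus conflict rule (summed score) and isobaric tie rule (keep
  observed) are deterministic stand-ins for expert manual curation.
- `?` insertion requires a pre-built reference alignment; no de novo
  multiple sequence alignment is performed.
- Greedy shared-peak matching can undercount dense ambiguous peak clusters
  relative to a maximum matching (never by more than half).
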