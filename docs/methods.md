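# Methods

`paleozyme` re-creates, on synthetic data with known ground truth, the
computational chain used to trace the deep-time persistence of enzyme
bi-functionality in the HisA/PriA sugar-isomerase superfamily: a sequence
similarity network of the superfamily, gene-neighbourhood screening and
species-wise gene concatenation, Bayesian phylogenetics with convergence
diagnostics, marginal ancestral sequence reconstruction, active-site motif
conservation, and steady-state enzyme kinetics.  This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Sequence evolution and the synthetic-data generators

Protein families are simulated along Yule (pure-birth) trees under empirical
time-reversible substitution models (JTT by default, WAG optional), with
branch lengths in expected substitutions per site — the same scale as the
tree figures this kind of study prints ("0.5 mutations per site").  The rate
matrix is `Q = S·diag(π)`, normalised to one expected substitution per site
per unit branch length; transition matrices come from the symmetric
eigendecomposition, so `P(t)` is exact, stochastic, and satisfies detailed
balance.  Optional rate heterogeneity uses the discrete-gamma approximation
(4 equal-probability categories, mean category rates).

Indels are simulated as a Poisson process at `indel_rate` events per site per
unit branch length, insertion:deletion 1:1, with geometric lengths (p = 0.3,
mean ≈ 3.3 residues) at uniform positions.  Insertions open fresh alignment
columns; deletions leave columns in place, so every node's sequence maps
consistently into one global column coordinate system and the simulator can
serve as an alignment and reconstruction oracle.  Every internal node's
sequence is retained (ungapped and in alignment coordinates).

The remaining generators define the study conditions for the downstream
stages:

- **Genomes.** A configurable fraction of species place hisA/hisF/hisH at
  consecutive gene-order indices (random internal order, shared strand);
  the rest scatter the markers with at least two intervening decoy genes or
  drop one marker.  Counts are exact by construction (`round(fraction × n)`).
- **Identity-block families** for network tests: each block descends from its
  own random ancestor and each member mutates each site independently with
  the probability `q` solving `(1−q)² + q²/19 = target identity`, so the
  expected pairwise identity within a block equals the target; between-block
  identity stays at the ~5% random background.
- **Progress curves**: numerical integration (LSODA, rtol 1e−9) of
  `dP/dt = kcat·E0·(S0−P) / (KM·(1+P/Ki) + (S0−P))` (plain Michaelis–Menten
  when Ki is absent), with additive i.i.d. Gaussian noise on the signal — the
  simplest model matching photometric assays — and `P(0) = 0`.

All generators are deterministic given their seed.

What the generators do **not** emulate: codon/nucleotide-level processes,
site-specific rate profiles (CAT-like mixtures), heterotachy, alignment
uncertainty from real homology ambiguity, database contamination and
fragmentary sequences, or enzyme hysteresis lags.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative models,
not robustness to every artefact of real data.

## Gene-neighbourhood screening and concatenation

A species is retained when its three marker genes lie on one contig with
gene-order span `(max − min + 1) − 3 ≤ max_intervening` (default 0, strict
adjacency).  The field convention "gene neighbours" does not fix strand or
internal order, so neither is constrained by default; both are configurable.
Duplicated markers exclude a species with a logged warning rather than an
error, since paralogy is common and silently picking one copy would be worse.
Concatenation order is HisF ⊕ HisA ⊕ HisH with 1-based inclusive partition
coordinates; partitions make the concatenation exactly reversible.

## Alignment and trimming

The progressive aligner builds a UPGMA guide tree from cosine distances
between 3-mer count vectors and merges profiles by global affine-gap
profile–profile alignment (expected BLOSUM62 column score; gaps −11/−1, the
standard gapped-BLAST parameterisation).  It replaces an external aligner at
desk scale; externally produced aligned FASTA is accepted as input instead.
Column trimming applies the single published rule — remove a column iff its
gap fraction strictly exceeds the threshold (default 0.5) — and records a map
back to untrimmed coordinates.  Conserved-flank/minimum-block rules of more
elaborate trimmers are deliberately out of scope.

Percent identity uses two conventions, stated per call site: identity over
the shorter sequence for greedy representative clustering (the CD-HIT
convention), identity over aligned columns for cluster statistics.

## Tree inference

The likelihood is the pruning (sum-product) algorithm with per-column
rescaling, gaps and ambiguity codes treated as missing data, and equal-weight
averaging over gamma categories.  Likelihood is invariant under re-rooting
(verified to 1e−8), as required for a reversible model.

Maximum-likelihood search is a desk-scale surrogate: neighbour joining on
pairwise ML distances (deterministic NJ backend), then alternating rounds of
per-branch Brent optimisation and best-improving nearest-neighbour
interchange, stopping when no interchange gains more than `tol`.  NNI ties
break on the first-encountered pivot in a fixed traversal, for determinism.

Bayesian sampling is Metropolis–Hastings over (topology, branch lengths):
random NNI (symmetric) with probability 1/2, otherwise a multiplier proposal
on one random edge (Hastings ratio = multiplier), under a uniform topology
prior and exponential(10) branch-length priors.  Defaults mirror the shape of
the published analysis — 4 chains, 10% burn-in — at a desk-scale default of
2000 samples.  The infinite CAT mixture of PhyloBayes is intentionally not
implemented; fixed empirical exchangeabilities (JTT/WAG) are a documented
simplification appropriate for a simulation-validated reimplementation.

Diagnostics follow the published workflow: `maxdiff` is the maximum over
chain pairs, across all nontrivial splits observed in any chain, of the
absolute split-frequency difference (whether the original tool applied a
frequency floor is not documented; all observed splits are used here).  ESS
is `N / (1 + 2Σρ_k)` with the autocorrelation sum truncated at the first
non-positive term, capped at N; a constant trace returns N with a warning.
The consensus tree is majority-rule (pooled frequency > 0.5) greedily
extended with compatible lower-frequency splits; supports are pooled
frequencies and trivial splits have support 1.  Outgroup rooting places the
root mid-branch on the edge separating a monophyletic outgroup.

## Ancestral reconstruction

Marginal reconstruction at a node combines the upward pruning partials below
it with downward partials from the rest of the tree: `P(state | data) ∝
up·outside`, normalised per column, with log-scale bookkeeping so gamma
categories are weighted by their true per-column likelihoods.  Marginal (not
joint) reconstruction is primary, matching the export convention of standard
ASR tools (per-node most-likely sequences).

Residue presence is reconstructed separately from the gap pattern under a
two-state reversible CTMC with equal equilibrium (0.5/0.5) and flip rate
`gain_loss_rate` (default 1.0 on the branch-length scale; not estimated).
Columns without any gap carry no indel signal and are assigned presence 1.
The most-likely sequence emits the argmax residue where the presence
posterior is ≥ 0.5 (ties favour presence; argmax ties break alphabetically),
and a gap elsewhere.  The MRCA of a singleton clade is defined as the leaf
itself; callers wanting its parent must ask for the parent's clade.

On simulated families (8–16 taxa, 300 columns, root-to-tip divergence ≤ 0.5
substitutions/site, 10 seeds) reconstructed ancestors average ≥ 90% identity
to the simulated truth (observed ≈ 97%), and accuracy decreases monotonically
with divergence.

## Sequence similarity networks

The pipeline mirrors the standard superfamily-network recipe: length window
230–260 (fragment removal), greedy longest-first collapse of sequences more
than 95% identical into representative nodes (strict >; exact duplicates
always merge), all-by-all local alignment, and edges at E ≤ 1e−54.  Local
alignments are exact Smith–Waterman (BLOSUM62, gaps 11/1), converted with
Karlin–Altschul statistics (λ = 0.267, K = 0.041, search space m·n per pair).
Because there is no composition adjustment or finite-size correction and the
search space is pairwise rather than database-wide, absolute E-values differ
from a BLAST database search; tests assert order-of-magnitude behaviour and
monotonicity, which is what thresholded network construction depends on.

## Motifs and logos

The eight active-site residues of the bi-functional isomerases (reference
motif D-R-E-D-R-G-W-D) are read off any homolog by mapping reference residue
positions through the alignment (k-th non-gap character → column).  Only some
slot numbers are resolved in print (E109, R143, W145 on the reference
structure), so the slot→position assignment is user configuration, not
hard-coded.  Matching is strict identity or up to residue equivalence classes
(basic {R, K}, acidic {D, E}) — a basic residue at the central arginine slot
is the biochemically relevant feature — and a gap never matches.  Logo
information content is `R = log₂20 − H(column)` with letter height
`frequency × R`, gaps excluded from frequencies, and no small-sample
correction (intended cluster sizes are large; the choice is documented and
the raw frequencies are exported).

## Kinetics

Initial-rate fits use nonlinear least squares on the Michaelis–Menten
hyperbola; when the data never approach saturation (max S0 below half the
apparent KM) only kcat/KM is identifiable and it is estimated from the
linear regime with a flag — the same convention the published table uses for
its weakest enzyme.  Progress-curve fits (for enzymes with hysteresis, where
initial rates are unreliable) fit all curves globally: the plain model by the
closed-form integrated Michaelis–Menten equation `P(t) = S0 −
KM·W((S0/KM)·e^{(S0−kcat·E0·t)/KM})`, evaluated via the Wright omega function
so large `S0/KM` cannot overflow; the product-inhibition model by inverting
its separable implicit solution `KM(1+S0/Ki)·ln(S0/(S0−P)) + (1−KM/Ki)·P =
kcat·E0·t` on a dense monotone grid (verified against ODE integration to
<1e−5 relative).  Product inhibition is modelled as competitive (inhibitor
term on KM) — the standard choice for products of this type; an uncompetitive
variant is deliberately not asserted as the original software's choice.
Parameters are fitted on the log scale (positivity by construction) from 5
log-spaced starts; standard errors come from the Jacobian at the optimum, and
an ill-conditioned Jacobian flags the fit as non-identifiable rather than
failing silently.  Efficiencies are reported as kcat/(KM·10⁻⁶) in 1/(M·s) to
2 significant figures.  Concordance between in-vitro efficiency and in-vivo
rescue time is Spearman rank correlation with midranks.

Published kinetic constants and complementation times for the extant and
ancestral enzymes are bundled as reference inputs; efficiencies are always
recomputed from kcat and KM because the printed efficiency exponents are not
reliably machine-readable.

## Study sizes and numerical choices

The validation studies run at sizes chosen to make each effect measurable
with comfortable statistical margin on a single CPU: 1000 columns for
branch-length recovery (per-branch sampling error ≈ √(t/n), so the 15%
recovery bound is assessed on the mean across branches, with the two root
child branches pooled — only their sum is identifiable); 6 taxa × 1000
columns with root-to-tip depth 0.8 substitutions/site and all branches
≥ 0.05 for the strong-signal posterior study (raw Yule draws can be saturated
or contain effectively zero branches, where no method could identify the
generating topology); 50 replicates at 2% noise for kinetic recovery; 10
seeds for ancestor recovery.  Branch lengths are bounded to [1e−9, 20] in all
optimisations; likelihood rescaling is per-column with accumulated log
factors; the pipeline manifest records parameters and SHA-256 checksums of
every output, and reruns with the same config and seed are byte-identical.

## Known limitations

- Fixed empirical exchangeability matrices; no site-heterogeneous mixture
  models, no partitioned models across the three gene segments.
- NNI-only tree moves (no SPR/TBR); the MCMC mixes slowly on large trees and
  its per-trace ESS at desk-scale sample counts is modest.
- The aligner is progressive without iterative refinement.
- E-values are internally consistent but not BLAST-calibrated.
- Real-data figures of the original study that depend on external databases
  (7824-sequence network counts, per-phylum motif percentages, the 430
  retained alignment positions) are inputs, not reproducible targets, and are
  not claimed by any test here.
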