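# paleozyme

Tools for tracing the evolutionary persistence of enzyme bi-functionality,
built around the HisA/PriA sugar-isomerase superfamily.  HisA and TrpF
catalyse analogous isomerisations (ProFAR→PRFAR in histidine biosynthesis,
PRA→CdRP in tryptophan biosynthesis); in Actinobacteria a single bi-functional
HisA homolog, PriA, performs both.  Asking whether such bi-functionality is
ancient requires a chain of computations — superfamily similarity networks,
gene-neighbourhood screening, Bayesian phylogenetics, ancestral sequence
reconstruction, active-site motif analysis, and steady-state kinetics of the
resurrected enzymes.  `paleozyme` implements that chain as a tested library
plus CLI, exercisable end-to-end on synthetic data whose ground truth
(ancestral sequences, gene neighbourhoods, cluster structure, rate constants)
is known exactly.

## What is inside

| module | contents |
| --- | --- |
| `seqsim` | Yule trees; sequence evolution under JTT/WAG (+gamma) with indels, all ancestors retained; synthetic genomes with controlled hisA/hisF/hisH synteny; identity-structured families; noisy Michaelis–Menten progress curves |
| `operon` | gene-neighbourhood scan (span rule), HisF⊕HisA⊕HisH concatenation with partitions, GFF3/TSV gene tables |
| `msa` | progressive profile aligner (BLOSUM62, affine gaps), >50%-gap column trimming, percent identity |
| `phylo` | pruning log-likelihood (rescaled, gaps-as-missing, discrete gamma), ML distances, neighbour joining, NNI hill-climbing with Brent branch optimisation, outgroup rooting |
| `mcmc` | Metropolis–Hastings tree sampling, split-frequency `maxdiff`, effective sample size, majority-rule consensus with supports |
| `asr` | marginal ancestral reconstruction (up/down passes), two-state indel reconstruction, most-likely ancestor extraction at a clade's MRCA |
| `ssn` | length filter, >95%-identity representative collapse, Smith–Waterman + Karlin–Altschul E-value edges, components with identity statistics |
| `motif` | structure-anchored position mapping, D-R-E-D-R-G-W-D motif matching with residue-equivalence classes, sequence-logo information content |
| `kinetics` | initial-rate and progress-curve fits (integrated Michaelis–Menten via Lambert W; competitive product inhibition), catalytic efficiencies, efficiency-vs-complementation-time rank concordance |
| `datasets` | published kinetic constants and complementation times used as worked-example inputs |
| `cli` | per-stage subcommands and `run-all` pipeline with manifests |

The core statistical machinery: the likelihood of an alignment `A` on a tree
`T` under a reversible model with rate matrix `Q = S·diag(π)` is computed by
the pruning recursion `L_v(x) = Π_c Σ_y P_{xy}(t_c) L_c(y)`, and the marginal
posterior of ancestral state `x` at node `v` is `P(x|A) ∝ up_v(x)·outside_v(x)`.
Progress curves follow `P(t) = S₀ − K_M·W((S₀/K_M)·e^{(S₀−k_cat E₀ t)/K_M})`.

## Worked example

```bash
paleozyme run-all --seed 7 --outdir out/
```

simulates ten species sharing a hisF/hisA/hisH operon along one Yule tree,
scans the genomes, concatenates, aligns and trims, infers an ML tree, runs
two MCMC chains with diagnostics, reconstructs all ancestors, builds a
two-block similarity network, computes motif logos, and fits simulated
progress curves.  It prints (numbers from an actual run):

```json
{
  "simulate": {"n_species": 10},
  "scan": {"passing_species": 10},
  "msa": {"columns": 239, "kept_columns": 208},
  "phylo": {"ml_loglik": -2919.53, "maxdiff": 0.0, "min_ess": 4.28},
  "asr": {"n_ancestors": 9, "mean_posterior": 0.947},
  "ssn": {"nodes": 12, "edges": 30, "components": 2},
  "motif": {"mean_information_bits": 3.23},
  "kinetics": {"kcat": 0.8999, "km": 27.99, "rank_concordance_trpf": -1.0}
}
```

Reading it: all 10 species pass the strict synteny scan (the generator placed
the operon in every genome); trimming removes the gappiest 31 of 239 columns;
`maxdiff = 0` says the two chains sampled indistinguishable split
frequencies; 9 internal-node ancestors are reconstructed with mean per-site
posterior 0.95; the identity-block family resolves into its 2 built-in
clusters; and the progress-curve fit recovers the generating constants
(kcat = 0.9 s⁻¹, KM = 28 µM — the ProFAR-isomerisation constants of
*S. coelicolor* PriA, used as simulation truth) to better than 0.1%.  The
rank concordance of −1 is the published observation that among the three
reconstructed ancestors, higher PRA-isomerisation efficiency means faster
rescue of a ΔtrpF strain.  `out/manifest.json` records every stage's
parameters and output checksums; a rerun with the same seed is byte-identical.

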