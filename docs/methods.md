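# Methods

## The model

Both analysis stages share one likelihood engine: a continuous-time Markov
chain (CTMC) on the states of a rooted ultrametric tree whose branch
lengths are in Myr.  A `RateModel` is a k-state generator Q defined by a
*class map*: every ordered off-diagonal pair (i, j) is assigned either a
rate-equality class or a structural zero, and one nonnegative rate per
class (units: expected events per Myr) fills the generator; diagonals are
set so rows sum to zero.  Transition matrices P(t) = exp(mQt) are computed
by one eigendecomposition per generator, applied to all branch lengths at
once, with a scaling-and-squaring (`scipy.linalg.expm`) fallback per branch
whenever the eigenvector matrix is ill-conditioned (condition number >
1e10) or the reconstruction leaves the stochastic simplex by more than
1e-9.  Rows are clipped to [0, ∞) and renormalised; for k ≤ 4 this is well
inside floating tolerance.

The probability of tip data is computed by the pruning (post-order
partial-likelihood) recursion with per-node rescaling, so alignments of
thousands of sites and trees of hundreds of tips stay in floating range.
Missing observations contribute a vector of ones; nucleotide IUPAC
ambiguity codes contribute the indicator of their compatible bases; gaps
are treated as fully missing.  Polytomies are handled naturally (product
over all children).  The root is weighted by a configurable rule —
`uniform` (1/k, the default), `stationary` (left null vector of Q), or a
custom vector.  The tool used in the original analyses does not document
its root treatment; uniform is the conventional default, and the
reproduction pipeline records the rule in every report so both variants can
be compared.

## Ancestral-state reconstruction

`MkAncestralReconstruction` fits the class rates by maximum likelihood:
`restarts` initial points drawn log-uniformly inside the rate bounds
(default [1e-8, 10] per Myr), L-BFGS-B in log-rate space from each, then a
Nelder-Mead polish of the best optimum.  The default of 100 restarts is a
desk-scale setting; the original analysis used 10,000 restarts of the same
scheme, and the restart count is an explicit parameter, so the fidelity
knob is documented rather than hidden.  Fits are deterministic given
`seed`.

Marginal ancestral probabilities use the standard two-pass (inside/outside)
algorithm at the MLE: the posterior of state s at node v is proportional to
the product of the upward partial likelihood at v and the outside
likelihood of the rest of the tree, normalised per node.  Both passes are
validated against brute-force enumeration over all internal-node state
assignments on small trees (max |Δ| ≤ 1e-8 in the acceptance suite).

The unit of analysis is the family: characters are scored per family
("present in at least one representative ⇒ present in the family") and the
default substrate is the 23-family collapsed chronogram.  Because the
original runs may instead have used the species-level tree with the family
state replicated across its representatives, `replicate_representatives()`
expands each family tip into n ≥ 2 tips at a configurable crown fraction,
and the reproduction pipeline accepts `tree_mode="replicated"`.

Preset completions where the published constraint sets are silent:

* model 1 names no class for p₁₂/p₂₁; the default folds them into the
  shift class (keeping the model at its three published equalities), and
  `separate_shift_12=True` frees them as a fourth class.
* model 2 constrains only trunk gains and trunk losses; the default groups
  the remaining head transitions as head-gain {p₀₁, p₂₃} and head-loss
  {p₁₀, p₃₂} (4 classes), and `six_classes=True` frees all four.

Every report embeds the full class map actually used, so these completions
are always auditable.

## Saturation reduction (DS1 → DS4)

Coding genes are translated with the standard genetic code; codons that are
all gaps give '-', codons with partial gaps or unresolvable IUPAC ambiguity
give 'X', and any codon that unambiguously encodes a stop raises an error
naming the taxon and codon index — silent stop translation would corrupt
the mixed amino-acid/nucleotide matrices written downstream.

Site-rate classification re-implements the gamma-category computation
itself rather than shelling out to an external program.  A GTR+Γ model is
fitted on the fixed chronogram topology: exchangeabilities (GT fixed to 1),
gamma shape α, and a single global substitution-rate scale (substitutions
per site per Myr — a strict-clock assumption appropriate for a chronogram;
an arbitrary substitution-branch-length tree can be supplied instead) are
optimised by L-BFGS-B from three spread starting scales, with empirical
base frequencies and alignment-pattern compression.  The discrete gamma
uses K equal-probability bins delimited by quantiles of Gamma(α, 1/α), each
category rate the conditional mean of its bin, exactly mean-1 (checked
against numerical quadrature to 1e-6).

A site's category posterior is empirical Bayes at the fitted (or supplied)
parameters: P(c | site) ∝ (1/K)·L_site(rate_c), and the assigned category
is the argmax with ties broken toward the slower category.  Constant
gap-free columns are always assigned category 1, since their likelihood is
decreasing in rate.  By default parameters are fitted per rRNA gene and
removal is applied jointly; passing explicit parameters forces joint
classification.  DS3 removes rRNA sites of category K from DS2, DS4
removes categories K-1 and K; the manifest records, per rRNA column, its
DS1 and DS2 coordinates, gene, category, and drop flags, which makes DS2
exactly reconstructible from DS3/DS4 plus the manifest (asserted across 50
randomized inputs in the acceptance suite).

## Synthetic data

The generators emulate the study conditions: 23-tip Yule chronograms with
the root rescaled to exactly 146.7 Ma (the published crown age of
Siluriformes); multi-gene alignments whose sites carry uniformly drawn
category labels (the equal-weight gamma mixture) and evolve under GTR+Γ
from a stationary root draw; and discrete characters evolved edge-wise by
exact transition-matrix sampling, with all internal-node states retained
for recovery scoring.  Default generator settings, chosen once as
realistic for this system and then left alone: gamma shape α = 0.4 and
branch scale 0.005 substitutions·site⁻¹·Myr⁻¹ for rRNA-like data (giving
root-to-tip expected divergence ≈ 0.7 at the mean rate, i.e. the
moderately saturated regime the method exists for), and binary-character
rates of order 0.01/0.005 per Myr.

What the generators do *not* emulate: per-gene model heterogeneity, indels
and alignment ambiguity, and the ~21% missing-data pattern of the real
matrix (an optional masking rate exists but defaults to off).  Passing the
synthetic tests therefore demonstrates correctness of the computations and
calibration under the assumed model, not robustness to real-data
violations of it.  In simulated coding genes, stop codons are repaired by
a deterministic third-position edit per taxon; this slightly breaks column
homology at those codons, which is irrelevant for the structural
(translation and bookkeeping) tests they serve.

## The bundled reference dataset and what reproduces

The 23-family chronogram is built from a fixed topology plus an MRCA-age
table.  The seven ingroup/deep ages are published point estimates
(Siluriformes 146.7 Ma, Diplomystidae–Siluroidei 142.2, Loricarioidei
123.8, Nematogenyidae+Trichomycteridae 114.0, CSAL 117.2, SAL 97.4,
Scoloplacidae+Astroblepidae 92.1).  The 15 Siluroidei crown ages were
published only as supplementary material; the bundle carries placeholder
values consistent with the published clade structure and the siluriform
chronogram literature, each flagged `source="placeholder"`, and every
report generated from the fixture propagates that flag.  The per-family
head-odontode codes are likewise supplementary-sourced; the defaults
(Loricariidae/Astroblepidae/Callichthyidae/Scoloplacidae 3, Nematogenyidae
2, Trichomycteridae 1, outgroups 0) are overridable, and reproductions
that differ only in such a cell should be read as sensitivity, not error.

Consequences, verified in this package's own runs and cross-checked
against an independent R implementation of the same likelihood: the
odontode reconstructions are driven by the printed ingroup ages and are
stable — model 2 gives P(trunk odontodes at the Loricarioidei MRCA) ≈ 1.0
under every variant, and model 1 gives ≈ 0.92 here versus 0.83 published.
The binary plates character, by contrast, is informationally marginal on
the 23-tip tree: its likelihood surface has a saturation plateau within
≈ 0.1 log unit of the interior optimum, and with placeholder outgroup ages
the MLE lands on the plateau, yielding near-stationary node posteriors
(≈ 0.70/0.30) rather than the published informative values (0.82, 0.97,
0.80, 0.72, 0.74).  Which side of that knife edge the fit falls on depends
on the exact outgroup node ages and on whether the species-level tree was
used, so the plates row of the comparison table must be interpreted with
its provenance flag.  The comparison table reports the absolute difference
for every published probability under the configuration actually run.

## Numerical and design choices

* Ultrametricity tolerance 1e-9 relative to root age; newick written with
  6 decimals; node ages (not branch lengths) are the primary
  representation.
* Rate bounds [1e-8, 10] per Myr on a log scale; optimisation in log-rate
  space; non-finite likelihoods penalised rather than propagated.
* Category ties break toward the slower category (argmax-first).
* Degenerate inputs fail loudly with the offending taxon/column/clade
  named: non-ultrametric trees, non-monophyletic collapse groups, unknown
  state symbols, internal stops, drop categories outside 1..K.
* Problem sizes in the acceptance suite (200-tip recovery trees, 2,000
  classified sites, 100 replicates, 50 DS-series seeds, 100 random oracle
  models) were chosen as the smallest sizes at which the statistical
  checks are stable.

## Known limitations

* No Bayesian (MCMC) reconstruction, stochastic mapping, or model
  averaging; no tree inference or divergence-time estimation — trees are
  inputs here.
* The GTR+Γ fit assumes a strict clock up to the fitted global scale when
  given a chronogram.
* DS1 is produced as a passthrough artifact for external tree programs;
  this package never analyses it further.
* The plates reconstruction on the bundled fixture is placeholder-age
  limited, as discussed above.
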