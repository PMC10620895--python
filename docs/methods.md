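# Methods

This note records the models and procedures implemented in `hergsar`, the
parameters that matter, and the design choices made where more than one
reasonable option existed.

## Activity standardisation and curation

IC50 values are converted to pIC50 = −log₁₀(IC50 in molar); accepted units
are nM, µM and M. Unlabelled units are read as nM — the convention of the
large public bioactivity databases this reader targets — with a warning
rather than a silent assumption of molar. Replicate measurements for one
compound identifier are collapsed to their median pIC50 by default
(`dedup="median"`); mean and first-value policies are available because
public data do not dictate a unique choice.

The balanced subset draw (`BalancedSubsetSelector`) produces a fixed-size
library whose activity histogram follows a normal curve over a stated
range, default [2.07, 9.85] log units:

1. records outside the range are dropped;
2. the Gaussian is parameterised by the in-range pool's mean and SD;
3. the range is cut into 0.5-log bins and each bin receives a quota
   proportional to the density at its centre, rounded by the
   largest-remainder method (floors first, then remainders, ties to the
   lower bin);
4. compounds are drawn uniformly without replacement within bins with a
   seeded generator; overflow quotas in underpopulated bins are pushed to
   the nearest bins with spare capacity, with a warning.

Largest-remainder apportionment is simple and sums exactly, but it is not
monotone in the target size in general (the Alabama paradox); the test
suite checks monotonicity only on instances where it holds. Bin width
0.5 log units balances resolution against per-bin occupancy for libraries
of a few hundred to a few thousand compounds.

## Heteroatom census and stratified effect analysis

The census counts every atom that is not carbon or hydrogen. All
heteroatoms — including F, Br, I, P — count toward the total, even though
only N, O, S and Cl are focal elements of the analysis; fluorine-rich
compounds would otherwise land in the wrong total-count strata. When both
a molecular graph and a formula are supplied, the census is computed from
the graph and cross-checked against the formula; disagreement is an error,
guarding against corrupt inputs. Formula parsing accepts linear Hill-style
strings only; parentheses, hydrates, isotopes and charges are rejected
with positional error messages.

A *stratum* is the set of compounds sharing (focal-element count, total
heteroatom count). Strata with fewer than 5 members (`min_size`) are
excluded as statistically unreliable. Effect detection compares all
stratum pairs with different focal counts within a comparison group and
flags those whose central pIC50 difference reaches `threshold` (default
0.9 log units — "around one log unit", set just below the smallest effect
the analysis is meant to notice). Two comparison modes exist because
"hold everything else fixed" is ambiguous:

- `mode="total"` (default): groups share the *total* heteroatom count, so
  raising the focal count trades against the other elements;
- `mode="other"`: groups share the count of *non-focal* heteroatoms, so
  totals differ between the compared strata.

Both the mean and the median are computed for every stratum. Detection
defaults to the **mean** and the median is available by flag; with skewed
activity distributions the two can disagree, and keeping both makes the
choice explicit rather than implicit.

For a flagged pair, the representative compounds are the minimum-pIC50
member of the weaker stratum and the maximum-pIC50 member of the stronger
one — the most extreme matched pair the two strata can produce. Ties on
pIC50 are broken by the lexicographically smallest identifier, making the
selection deterministic and auditable.

`trend_summary` pools the members of all qualifying strata per focal count
and reports the central pIC50 curve with a verdict. The curve is called
*non-monotone* when it both falls and rises by at least `reversal_tol`
(default 0.2 log units) around an interior extremum — the turning point is
reported; curves whose full span is below `flat_tol` (default 0.05) are
*flat*; otherwise the sign of the Spearman rank correlation decides
increasing vs decreasing. Two tolerances are needed because a genuine but
small monotone effect (e.g. a −0.15/atom slope) must not be mistaken for
noise-level flatness, while noise wiggles of a few hundredths must not be
promoted to reversals.

## Fingerprints and kernels

Four sparse topological fingerprint families are computed directly from
the heavy-atom graph (hydrogens implicit):

- **atom pairs** — (type_i, type_j, shortest-path distance) per unordered
  atom pair; cross-component pairs of a disconnected graph are skipped
  with a warning;
- **linear** — canonical simple paths of 1..7 bonds, keyed by the
  atom/bond string read in the lexicographically smaller direction;
- **radial** — Morgan-style circular environments for radii 0..3, with
  order-independent neighbour combination; an atom stops emitting once its
  environment stops growing, so an isolated atom contributes one feature;
- **torsions** — canonical four-atom linear paths;

plus the public 166-key structural-key set matched via SMARTS (chain-form
approximations for the few keys whose official definitions involve
ring-closure special cases; the module docstring lists them). The default
atom type is (element, heavy degree, aromatic flag); an element-only mode
exists so small-molecule tests can be enumerated by hand. Path length 7
and radius 3 are conventional defaults for activity modelling; no claim is
made that they match any proprietary fingerprint implementation.

Feature keys are canonical strings digested with BLAKE2b under a fixed
salt, so fingerprints are identical across runs and platforms. The sparse
key→count representation is kept (no folding), which makes Tanimoto and
minmax kernels exact; an optional fold to a fixed-length count vector
serves dense kernels and ordinary sklearn pipelines.

Kernels: Tanimoto |A∩B|/|A∪B| on binary supports (defined as 1 when both
are empty), minmax Σmin/Σmax on counts, Gaussian and linear on dense
vectors. Tanimoto is the default for chemical similarity. Both set
kernels are symmetric, unit-diagonal and positive semidefinite (checked
to an eigenvalue tolerance of −1e−8 in tests).

## Kernel PLS

The regressor implements the dual (kernel) NIPALS sequence: the training
Gram matrix is double-centred; each component takes the score direction
t ∝ K_res y_res, deflates K_res ← (I − ttᵀ) K_res (I − ttᵀ) and the
response residual, and the dual coefficients are assembled as
α = U (Tᵀ K U)⁻¹ Tᵀ y with test kernels centred by the training
statistics. Deflation stops early, with a warning, when the candidate
score variance falls below 1e−12; the achieved component count is
recorded. With a linear kernel and the full component count the model
reproduces ordinary least squares (with intercept) — this equivalence is a
test oracle, checked against an independent OLS fit.

The number of components defaults to `"auto"`: the value in 1..10 that
maximises 5-fold internal Q² on the training set. Q² on held-out data is
computed as 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)² with the *training* mean as
reference — the external-validation convention; using the test mean
flatters models on small test sets. The composite ranking score
min(R², Q²) − ½|R² − Q²| (clipped to [0, 1]) is this package's own
surrogate objective for ordering candidate models: it rewards accuracy on
both sets and penalises train/test gaps. It is used only for ordering,
never for fitting.

Atom-level attributions: the contribution of atom *a* is the prediction
drop when every fingerprint feature occurrence whose substructure contains
*a* is removed. This is a leave-atom-out ablation in feature space, not a
gradient; symmetric atoms receive identical values by construction, and a
zero-component model attributes zero everywhere.

## Synthetic libraries

The generator emulates a curated activity library as heteroatom
compositions over {N, O, S, Cl, F} on saturated acyclic C/H scaffolds,
with the additive planted model

    pIC50 = base + βO·nO + βS·nS + βCl·nCl + g(nN) + ε,  ε ~ N(0, σ²),

clipped to [2.07, 9.85]. Defaults: base 6.0, βO = −0.30, βS = +0.35,
βCl = −0.15, σ = 0.4, and g = {0:0, 1:0, 2:−0.4, 3:−0.8, 4:−0.5, 5:−0.2} —
monotone down from 1 to 3 N and up from 3 to 5 N. The slope magnitudes are
chosen so a 3–4 atom difference crosses the ~1 log-unit detection
threshold, matching the effect sizes such an analysis is designed to
flag. Above 5 N the model represents instability as inflated noise
(σ × 3); fluorine is activity-neutral and serves as composition filler.

Compositions come from a designed-cell law plus uniform background over
the ranges N 0–5, O 0–4, S 0–1, Cl 0–1, F 0–3, totals 4–11. The designed
cells guarantee (≥ 5 members each, scaled with library size) the stratum
contrasts the analysis needs: an oxygen series O = 0..4 at total 6, a
nitrogen series N = 1..5 with three fluorines, and matched
presence/absence cells for S and Cl. Structural realisations are acyclic
SMILES (amine/ether/thioether links, halide substituents) whose parsed
census round-trips exactly.

What the generator does **not** emulate: assay heterogeneity and unit
mixtures, ring systems and aromatics in the planted response, activity
cliffs beyond heteroatom composition, or any correlation between scaffold
size and potency. Passing tests therefore demonstrate that the pipeline
recovers composition-level effects it was pointed at — not that real hERG
data obey an additive heteroatom model.

## Problem sizes and determinism

Test and acceptance runs use libraries of 1000 compounds (100 seeded
replicates for recovery rates), a 2000-compound pool subset to 508 for
the QSAR stage, and an 85/15 train/test split — sizes at which every
stratum cell of interest is populated and the full suite runs in well
under a minute of kernel algebra. All stochastic steps take explicit
seeds; pipeline outputs carry a provenance header (version, seed, config
hash) and contain no timestamps, so a rerun with the same configuration
is byte-identical.

## Known limitations

- The structural-key set diverges from other toolkits on a handful of
  ring-closure corner cases (documented in `hergsar.maccs`).
- Effect detection reports marginal associations within strata; at a fixed
  total, raising one element necessarily lowers another, so flagged
  effects are contrasts between compositions, not causal atom effects.
- Kernel PLS component selection uses a fixed internal CV partition
  (seeded) rather than repeated CV; on small training sets the selected
  component count can vary with the seed.
- `gen_smiles` produces acyclic molecules only; censuses requiring rings
  or elements outside {N, O, S, Cl, F} are rejected as unrealisable.
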