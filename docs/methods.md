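# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Pathway model for electronic coupling

The structural arm estimates the *relative* electronic coupling between
two redox cofactors with the empirical tunneling-pathway model: a
pathway is a chain of steps, each contributing a unitless decay factor
ε, and the coupling is the product of the factors. The step classes and
defaults (all overridable through `DecayModel` or the `decay:` config
block):

| step kind | ε | parameters |
|---|---|---|
| covalent bond | 0.6 | distance-independent |
| hydrogen bond | min(0.36, 0.36·e^{−β(r−2.8)}) | β = 1.7 Å⁻¹, r = heavy-atom distance |
| through-space | min(0.6, 0.6·e^{−β(r−1.4)}) | β = 1.7 Å⁻¹ |

These are the classic pathway-analysis constants for protein electron
transfer (a hydrogen bond counted as two covalent bonds squeezed to its
heavy-atom distance; through-space decay referenced to a 1.4 Å contact).
The caps keep ε ≤ its covalent-limit value when a contact is unusually
short. This is an intentionally coarse, auditable stand-in for
electronic-structure tunneling calculations: absolute couplings are not
meaningful, but ratios between structures that differ by a few atoms
are dominated by the geometry the model does capture. Results should be
read as qualitative trends, which is also how ab initio treatments of
Fe–S systems present theirs.

**Why rate ∝ T².** In the nonadiabatic golden-rule picture the rate is
k = (2π/ħ)|T_DA|²·FC. A side-chain truncation at a bridging residue
leaves the donor, the acceptor, the driving force, and (to the accuracy
of this model) the Franck–Condon factor unchanged, so everything cancels
in the ratio except |T_DA|²: k_WT/k_mut = (T_WT/T_mut)². No absolute
rates are ever reported.

**Graph construction.** Nodes are all heavy atoms; hydrogens are ignored
throughout (crystallographic and cryo-EM structures of this size rarely
resolve them, which is also why the hydrogen-bond test is a pure
distance window of 2.4–3.5 Å over N/O/S pairs in different residues,
with no angle term). Covalent bonds come from the usual radius-sum
criterion (r_i + r_j + 0.45 Å, with a 0.4 Å clash floor). Non-bonded
heavy-atom pairs within 6.0 Å get a through-space edge; beyond that
ε_sp < 2.5·10⁻⁴ and a jump cannot compete with any two-step alternative,
so the cutoff only removes hopeless edges (widening it can only increase
the best coupling, and a property test asserts exactly that). All atoms
of each cofactor are contracted into one super-node — the cluster
orbitals are treated as fully delocalized (intra-cluster ε = 1), which
makes "where does the path start" well-defined; an edge incident to a
super-node takes the strongest contact over its member atoms.

**Search and determinism.** The maximum-product path is found as a
shortest path under weights −ln ε (Yen's algorithm supplies ordered
candidates). Ties within a relative 1e-12 in coupling are broken by
fewer steps, then by the lexicographically smallest atom-serial
sequence, so outputs are byte-stable. Only the single dominant path is
scored; interference between near-degenerate parallel pathways is not
summed (`top_k_paths` exists for diagnostics). Disconnected
donor/acceptor pairs yield an explicit T = 0 "no pathway" result, and a
mutation that disconnects the only route reports an infinite ratio with
a `disconnected` flag rather than raising.

**Structure handling.** Files are parsed with gemmi (PDB or mmCIF),
model 1 only, author residue numbering as printed in the file (the
literature cites per-species residue numbers, so no renumbering is ever
applied). Altloc duplicates keep the highest occupancy, ties broken by
file order. Waters are excluded by default: water-mediated pathways are
a real possibility in a truncation cavity, but whether a water occupies
the site is unknowable from the input structure, so it is an explicit
opt-in (`include_waters`) rather than a silent default.

**Mutagenesis.** Substitutions are pure truncations: the residue is
renamed and atoms outside the target's canonical heavy-atom set are
deleted. No rotamer rebuilding or minimization — deterministic, and it
guarantees the mutant atom set is a subset of the wild type's, which in
turn guarantees T_mut ≤ T_WT and ratio ≥ 1 (tested across 100 generated
structures). Substitutions that are not truncations are rejected; this
includes Phe→Leu, where the target's atom *names* happen to be a subset
of the source's but the shared CG/CD1/CD2 change from aromatic to
aliphatic carbons — a ring-membership table catches such name
coincidences. Stability effects of mutations (ΔΔG) are out of scope.

## Synthetic bridge fixture

`make_bridge_structure` builds the situation the structural arm is
meant to resolve: two 4Fe–4S cubane mimics (8 atoms each, residue SF4)
whose nearest atoms are ~7.5 Å apart — beyond the space cutoff — with a
single bridging residue whose side chain closes the gap in two ~3 Å
jumps plus covalent steps, and a two-glycine backbone decoy route that
is weaker by construction (longer end gaps, four covalent steps). A
valine bridge (CG1–CB–CG2) supports Val→Ala/Val→Gly; an aspartate
variant (CB–CG with carboxylate oxygens pointed away from the clusters)
supports Asp→Gly. All coordinates sit on a 0.001 Å grid so that the
values written to PDB text re-read exactly; the generator evaluates a
fixed inventory of designed routes with the same step rules and records
the best as analytic ground truth (best-path atoms, per-step distances,
T_WT, T_mut, rate ratio). The full pipeline — file parsing, bond
inference, graph search — reproduces these products to 1e-9 relative.
A seed-driven jitter (up to 0.4 Å, shifting the acceptor cluster and
distal side-chain atoms) varies batches of structures without reordering
the designed routes. The fixture's Val→Ala ratio is ~70-fold at zero
jitter; the published calculation for the ovine enzyme's N4→N5 pair
reports 35-fold with an ab initio method, so the fixture reproduces the
order of magnitude and the mechanism (the bridging valine carries the
path), not the exact figure — which a different coupling model cannot
be expected to match. Mapping cofactor labels (N4, N5, …) to residues
in a *real* deposited structure requires curation by the user; the
package never guesses it.

## Omics statistics

The pipeline follows the standard label-free quantification workflow.
Filtering keeps features with 100% valid values in at least one group
(a feature absent in patients but complete in controls is biology, not
a missing-data problem). Imputation then draws each sample's missing
values from Normal(mean − 1.8·SD, (0.3·SD)²) of that sample's observed
log2 values — the conventional down-shift parameters for
left-censored missingness; both numbers are exposed in the config.
Per-feature tests are Student's equal-variance two-sample t-tests by
default (the convention of the common proteomics platforms; Welch is a
flag), with Benjamini–Hochberg q-values and 0.05/0.05 thresholds.
Features with zero variance and equal means in both groups get p = 1 by
convention. Redox ratios are compared on per-sample log2(GSH/GSSG) by
one-way ANOVA plus Tukey HSD (studentized-range quantiles, α = 0.05).

**Enrichment.** Running-sum scores use hit increments ∝ |log2FC|^p with
p = 1 (the common tool default) normalized to 1, miss decrements
1/(N−N_hit), ES = signed maximum deviation; sets smaller than 5 after
intersection with the measured universe are excluded. The null is
*gene-set permutation* (random same-size sets), not phenotype
permutation: with triplicates there are only 10 distinct two-group
label splits, far too few to estimate a tail. Nominal p is the
one-sided tail frequency among same-signed null scores with +1
smoothing — under random sets this construction is uniform, which a
dedicated test verifies by KS at α = 0.01 over 500 runs. q is BH across
the scored sets.

**Curated CI module lists.** `ci_modules.py` ships a hand-curated
assignment of human CI subunit gene symbols to the N, Q, and P modules
following consensus structural assignments. Interface subunits are
judgment calls; the lists are a convenience default, not a measurement,
and callers can pass their own sets everywhere.

## Synthetic omics generator

`make_omics_table` draws per-feature baselines from Normal(23, 2²) in
log2 units (typical LFQ intensity scale), applies planted per-group
multiplicative effects, adds replicate noise with log-normal sd derived
from the stated CV (σ_ln = √ln(1+CV²)), and optionally censors values
with a logistic abundance-dependent dropout. Defaults mirror the study
conditions this package targets: triplicate groups; CV 10% for
proteome-like and 15% for metabolome-like tables (consistent with the
very high replicate correlations such experiments report); a
121-feature metabolome with GSH planted 12-/16-fold down and GSSG
2.2–3-fold up in the two patient groups so the GSH/GSSG ratio drops
>35-fold; a 400-feature proteome containing every curated CI subunit
with the 11 N-module members depleted 3–10-fold (the four
literature-named subunits at 3/4/6/10, the rest spread across that
range) and Q/P untouched.

What passing these benchmarks shows: the statistics are calibrated
(type-I error 5% ± Monte-Carlo error under the null; BH equals the
step-up definition; enrichment p uniform) and powered at the planted
effect sizes (a 16-fold depletion at triplicate scale is BH-flagged in
>95% of runs; the N-module set is flagged specifically). What it does
not show: robustness to the things real LC-MS data add — correlated
features, batch effects, intensity-dependent variance, peak-integration
artifacts. The generator makes no attempt at noise physics, and
conclusions about real data need the usual diagnostics.

**A note on the ANOVA permutation check.** The test comparing the
parametric ANOVA p against a label-permutation oracle uses 6 replicates
per group: at triplicate scale the permutation null has too few distinct
values to approximate the F distribution, so triplicate data rely on the
normality that the log transform provides.

## Problem sizes

Default simulation sizes — 200 random graphs for the search oracle, 100
structures for monotonicity, 200 simulations for calibration and power,
500 runs for p-uniformity, 1000 permutations for enrichment — were
chosen so the Monte-Carlo error on each checked quantity is comfortably
below the tolerance being asserted, and the whole suite plus the
acceptance script run in well under a minute of compute.

## Known limitations

- Single-path scoring ignores pathway interference; near-degenerate
  routes (common in beta sheets) can make single-path ratios too sharp.
- The decay constants are generic; specific systems (notably Fe–S
  clusters with strong spin coupling) may deviate systematically. Only
  ratios between closely related structures should be interpreted.
- Truncation-only mutagenesis cannot model substitutions that add or
  re-hybridize atoms, nor side-chain repacking or water entry into the
  cavity (an optional water-placement flag is deliberately not a
  default).
- The omics arm assumes the input table is already normalized
  (internal standards / total protein); no normalization is applied.
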