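# Methods

## The model

A protein's mechanical couplings are represented by a backbone/side-chain
elastic network (bsENM): every residue contributes a coarse-grained (CG)
site at the amide nitrogen, one at the carbonyl oxygen, and — except for
glycine — one side-chain site (a representative interacting atom for
polar/charged residues, the heavy-atom center of mass for hydrophobic
ones).  Structural ions and ligand residues enter as single-site extra
residues.  Sites i, j with mean separation l⁰ᵢⱼ below a cutoff l_c
(default 7.8 Å) are joined by a harmonic spring of stiffness kᵢⱼ
(kcal·mol⁻¹·Å⁻²).  Setting every within-cutoff kᵢⱼ = 1 yields the
topology-only reference network ("bsENM₀"), whose inter-residue degree is
the familiar contact number.

Normal-mode analysis is realized as the eigendecomposition of the 3N×3N
Hessian; each spring contributes −k·êêᵀ off-diagonal with ê the unit
vector along the equilibrium separation.  Classical equilibrium
fluctuations of a harmonic network are mass-independent, so no masses are
carried: the site covariance is C = k_B·T·H⁺ with the rigid-body null
space (6 modes; 5 for collinear geometries) excluded by an eigenvalue
threshold of 10⁻⁸ × the largest eigenvalue.  The predicted variance of an
inter-site distance is the first-order projection
⟨δl²ᵢⱼ⟩ = êᵀ(Cᵢᵢ + Cⱼⱼ − 2Cᵢⱼ)ê,
exact for the Gaussian model in the small-fluctuation limit.
k_B is taken as 1.987×10⁻³ kcal/mol/K, so k_B·T = 0.5961 kcal/mol at the
default 300 K.

## Statistical learning of spring constants

Spring constants are matched to per-pair distance variances observed in a
trajectory window (population variance over frames; rest lengths are the
window-mean distances).  The self-consistent update per iteration is

    k ← max(0, k + α·k_B·T·(1/⟨δl²⟩_target − 1/⟨δl²⟩_model)),

which for an isolated pair is a damped Newton step on the closed form
k = k_B·T/⟨δl²⟩.  Coupled springs make the raw iteration oscillate
(a spring bundle overshoots to zero, the local variance explodes, the
update slingshots back), so two stabilizers are used:

* a per-spring trust region, |Δk| ≤ max(0.5·k, α/α₀) — springs change by
  at most 50% per step once established, while still being able to leave
  zero;
* a best-state restart guard: if the maximum relative variance mismatch
  fails to improve on its best value for 10 consecutive iterations, the
  iterate is reset to the best state seen and α is halved.

Convergence is declared when the maximum relative mismatch over springs
with k > 0 falls below 10⁻⁶ (default; max 3000 iterations, α₀ = 0.5).
The tight tolerance is deliberate: the variance → stiffness map is
ill-conditioned (see *Identifiability* below), so a loose variance match
can hide percent-level stiffness errors.  Against analytic targets of a
30-residue reference the learner recovers every spring with k_ref > 0.1
to better than 0.2%.

Connectivity trimming then removes springs with k < k_min (default 10⁻³)
— skeleton-1 springs exempted to preserve chain connectivity — and reruns
the matching on the survivors; disconnection is detected by Hessian rank
and refused with a suggestion to lower k_min.

### Identifiability of individual springs

With ~10⁴ frames the relative standard error of a variance estimate is
√(2/n) ≈ 1.4%.  Propagating independent variance noise through the
linearized inverse map (Jacobian J_pq = −(1/k_BT)·(k_BT·w_pᵀH⁺w_q)², with
w_p the signed pair-difference direction) shows that springs running
nearly parallel between the same residue pair — e.g. the up-to-nine
springs joining two residues' three sites each — are individually almost
unidentifiable: their stiffness uncertainty reaches tens of percent even
though their *sum* (the inter-residue edge weight k_IJ used by all graph
analyses) is well determined.  This is a property of the inference
problem, not of the optimizer: the same runs recover the analytic-target
fixed point to <0.2%.  Consequently, spring-level Monte-Carlo recovery is
validated at the median (a few percent) and at the residue-sum level, not
at the worst spring.

## Rigidity graphs

Springs are classified by residue separation — skeleton-1 (within a
residue or between sequence neighbours), skeleton-2 (second neighbours),
non-skeleton (all else; inter-chain pairs always) — and by chemistry
(cysteine Sγ–Sγ pairs with rest length < 2.5 Å are disulfides, excluded
from non-skeleton analyses as covalent).  The endpoint site classes give
the interaction group: BB, BS, or SS.

The inter-residue adjacency sums spring constants over site pairs,
A_IJ = Σ_{i∈I, j∈J} kᵢⱼ; D holds row sums; L = D − A and K = D + A.
Both the group decomposition (A_ALL = A_BB + A_BS + A_SS) and the
skeleton/non-skeleton decomposition are exact by linearity.  All spectral
analysis uses K of the non-skeleton springs: the low modes of L are
dominated by the skeleton/topology (for chain-regular folds they coincide
with those of the contact network L₀), whereas K exposes the specific
strong couplings.

## Windowed statistics, prominent modes, hotspots, scores

A trajectory is cut into consecutive, non-overlapping windows (trailing
partial windows dropped; the conventional choice is 10 ns at a 1 ps save
interval → 10⁴ frames).  Per-window graphs K_n are averaged entrywise to
K̄; its eigenvectors (descending eigenvalue, deterministic sign) are the
mean-modes.  The content of mean-mode α′ in window n is
r_n^α′ = max_β |ν_n^β·ν̄^α′| ∈ (0,1] — sign-flip invariant by
construction; degenerate eigenvalues are logged since contents inside a
degenerate subspace are basis-dependent.

A mean-mode is *prominent* when (a) its strength exceeds the Tukey upper
fence Q3 + 1.5·IQR of the eigenvalue distribution (strict inequality;
quantiles by linear interpolation, numpy's default "type 7" — stated
because fences move with convention) and (b) its averaged content is in
the top quantile (default top 25%; top 32% for SS graphs, whose contents
fluctuate more).  Residues with squared weight ν_I² ≥ ν_c² (default 0.1)
in a prominent mode are the mechanical hotspots; normalization caps the
hotspot count at ⌊1/ν_c²⌋.

Each residue's characteristic mode is the prominent mode where it carries
the most weight, if that weight reaches ν_c²; otherwise the best
non-prominent mode (argmax ties break toward the smaller index).  Its
rigidity score is κ_I = ⟨r⟩·λ of that mode.  Backbone/side-chain scores
combine the groups: κ^B = max(κ^BB, κ^BS), with κ^BS admitted only if the
residue enters its BS characteristic mode through its backbone; κ^S
symmetric.  "Enters through its backbone" is operationalized as ≥50% of
the residue's non-skeleton BS strength toward the mode's hotspot partners
arriving via its backbone sites (falling back to all of its BS springs
when no hotspot partner is connected) — the choice is configurable since
the concept admits several formalizations.  Glycine, lacking a side-chain
site, reports κ^S as a configurable minimal placeholder (0 internally).

Secondary-structure location classes consume external per-residue H/E/L
labels: *interior* = inside a helix/strand and more than `margin`
(default 3) residues from both ends; *periphery* = within `margin` of an
element boundary, inside or outside; *loop* otherwise.

## Heavy-tail statistics

The Lomax (shifted-Pareto) distribution p(x) = (α/s)(1+x/s)^−(α+1) is
fitted to the full positive sample by profile maximum likelihood: for
fixed scale the shape MLE is closed-form, leaving a bounded 1-D search in
log-scale.  Exponential-like samples drive the scale to the bound and the
shape large; that is reported as a converged fit, not an error.  The
power-law tail exponent uses the continuous (Hill) MLE
γ = 1 + n/Σln(x/x_min); when x_min is not supplied it is scanned over the
unique sample values between the 50th and 95th percentiles (keeping ≥20
tail points) and chosen to minimize the KS distance, Clauset-style.  Both
variants are exposed because published fits rarely state their range
convention.  Bootstrap goodness-of-fit p-values are out of scope; the KS
distance is reported.

## The synthetic data generator

Real long-trajectory inputs for this kind of analysis are rarely shared,
so the package ships a generator whose outputs stand in for them at test
time, with known ground truth:

* **Geometry.** A compact self-avoiding chain (step 3.8 Å, minimum
  non-neighbour separation 3.9 Å, confinement radius 2.8·N^⅓ Å — globular
  protein density), with N/O sites split ±1.2 Å along the local tangent
  and a side-chain site 2.4 Å outward; or an ideal α-helix (2.3 Å radius,
  1.5 Å rise, 100°/residue).  The globule is the default wherever dynamics
  matter: at protein-like density the softest internal mode stays near
  0.5–1 kcal·mol⁻¹·Å⁻², keeping the 300 K Gaussian ensemble inside the
  small-fluctuation regime.  The helix is the clean setting for chain-mode
  comparisons: its banded, translation-regular contact map makes the
  low-frequency modes of the skeleton Laplacian and of the contact
  Laplacian coincide (r > 0.95), the idealization of a fold whose spatial
  clusters are sequence-contiguous.
* **Spring constants.** Skeleton-1 U(10,50), skeleton-2 U(5,20)
  kcal·mol⁻¹·Å⁻² (peptide-bond scale vs. weaker second-neighbour
  bracing); non-skeleton springs are zero with probability increasing
  linearly with distance (mean level = `zero_fraction`, default 0.2 —
  longer contacts are rarer), otherwise 0.05 + Lomax(shape 2.2, scale 1.0).
  The 0.05 floor keeps true springs cleanly separated from the 10⁻³ trim
  threshold; the shifted-Lomax law is what the KS self-test checks.
* **Trajectories.** Frames are drawn i.i.d. from N(equilibrium, k_B·T·H⁺)
  with zero variance along rigid-body modes.  Fluctuation matching
  consumes only variances, so the absent temporal autocorrelation cannot
  affect its correctness; window-level fluctuation is instead emulated
  directly by multiplying spring constants with independent lognormal
  noise per window, one sequence-distant edge planted constant and
  dominant (6× the 99th percentile) so prominent-mode detection has a
  known answer.

What passing these tests does *not* show about real data: anharmonicity
(real MD distance fluctuations are not Gaussian — at 300 K weakly coupled
pairs in the fixture itself already show percent-level bias between
sampled and linearized variances, which is why strict loop-closure tests
run at reduced temperature), temporal correlation between windows, and
solvent/chemistry effects that make real spring constants what they are.

## Problem sizes and numerical choices

Default study sizes used by the tests and the acceptance script: a
30-residue (90-site, ~1300-spring) reference for learning and graph
statistics, 12 residues for unit-level recovery, 10⁴ frames per sampled
window, 20 windows × 10 seeds for hotspot statistics, 10⁵ draws for
distribution-fit recovery.  Eigendecompositions use `numpy.linalg.eigh`;
zero modes are identified relative to the largest eigenvalue (10⁻⁸);
distance ties and argmax ties break toward the smaller index everywhere.
Degenerate inputs (coincident connected sites, disconnected networks,
all-equal samples, sub-quartile mode counts) raise informative errors
rather than returning silent numbers.

## Known limitations

* Individual spring constants inside parallel bundles are not identifiable
  from finite sampled variances (see above); residue-level sums are the
  robust observable.
* The first-order distance projection omits anharmonic corrections; no
  resampling-based variance predictor is provided.
* Secondary structure is consumed, never assigned; sequence co-evolution
  analyses are out of scope.
* The fluctuation-matching update is the standard inverse-variance rule;
  alternative updates (force matching, relative-entropy minimization) are
  not implemented.
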