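# Methods

## The model

`thfkin` implements a deterministic kinetic model of the terminal steps
of tetrahydrofolate (THF) biosynthesis, built to study a folate-damage /
repair loop: a side activity of ketopantoate hydroxymethyltransferase
(PanB) that cleaves 5,10-methylene-THF (CH2-THF), and the recycling of
the released pterin moiety back into the pathway through
6-hydroxymethyl-7,8-dihydropterin pyrophosphokinase (FolK).

The network has ten reactions:

| id | reaction | rate law |
|----|----------|----------|
| SRC_HMPt | ∅ → H2-HMPt | constant flux v_net |
| SRC_pABA | ∅ → pABA | constant flux v_net |
| FolK | H2-HMPt + ATP → H2-HMPt-PP + AMP | irreversible mass action |
| FolP | H2-HMPt-PP + pABA → H2-pteroate + PPi | irreversible mass action |
| FolC | H2-pteroate + ATP → DHF + ADP + Pi | irreversible mass action |
| FolA | DHF → THF | irreversible mass action |
| GlyA | THF + Ser ⇌ CH2-THF + Gly | reversible mass action (near equilibrium) |
| PanB_side | CH2-THF → H2-HMPt + pABA | irreversible mass action |
| DRAIN_THF | THF → ∅ | saturating irreversible (vmax, km) |
| DRAIN_CH2THF | CH2-THF → ∅ | saturating irreversible (vmax, km) |

Seven cofactor/cosubstrate pools (ATP, ADP, AMP, phosphate,
pyrophosphate, serine, glycine) are held at fixed physiological
concentrations and excluded from the ODE state; the seven remaining
species (the six pterin-containing intermediates plus pABA) are dynamic.
Units are mmol·ml⁻¹ cytoplasm (numerically mol·L⁻¹) for concentrations,
seconds for time, mmol·ml⁻¹·s⁻¹ for fluxes.

Modeling assumptions:

- **Unsaturated enzymes.** FolK, FolP, FolC, FolA and the PanB side
  reaction are far from saturation in vivo, so simple mass action (rate
  ∝ reactant concentrations) is used; `make_saturated_variant` verifies
  that saturating re-modelings with vmax above the operating flux give
  the same steady states to a few percent.
- **GlyA near equilibrium.** The forward flux (~3.7e-4 mmol·ml⁻¹·s⁻¹ at
  defaults) exceeds the net flux by ~3 orders of magnitude, so the
  [CH2-THF]:[THF] ratio is pinned at kf·[Ser]/(kr·[Gly]). This is the
  lever controlling the ratio of the two folate pools.
- **Growth dilution as saturating drains.** The consumption/dilution of
  THF and CH2-THF during growth is a Michaelis–Menten sink per species.
  Drains cannot be constant fluxes: with a constant source and constant
  sinks the pool sizes would be indeterminate (or the system overdetermined),
  whereas saturable drains let the pool sizes settle where outflow
  balances the source.
- **pABA moiety recycling.** The cleavage product of the side reaction
  is pABA-Glu. Its hydrolysis back to pABA is treated as instantaneous
  and glutamate is untracked, so the reaction is written
  CH2-THF → H2-HMPt + pABA. This is not merely a convenience: because
  FolP consumes pABA at the full pathway flux v_net + v_PanB while the
  exchange reaction supplies it at v_net, a model that discards the pABA
  moiety has **no steady state** whenever the cleavage flux is positive.
- **Cofactor lumping.** Glutamate (FolC) and NADPH/NADP⁺ (FolA) are not
  tracked; their constant concentrations are absorbed into the
  respective rate constants. Water is omitted (activity 1). Folate
  polyglutamylation is outside the model's scope.
- **Redox shortcut.** The cleavage actually yields the tetrahydro form
  of the pterin; its oxidation to the dihydro form (the FolK substrate)
  is taken as instantaneous, so a single recycled species enters FolK.

## Steady states and the conserved direction

The ODE is dx/dt = S·v(x) over the dynamic species. Steady states are
found by damped least-squares root finding in log-concentration space
(Levenberg–Marquardt on the scaled residual, positivity by
construction), with a relaxation fallback: staged stiff integration
(LSODA, rtol 1e-10 / atol 1e-14) until the residual is small, then the
same polish. Convergence requires max |d[X]/dt| < 1e-6·v_ref (v_ref is
the constant source flux for the reference model); the polished residual
is typically at the 1e-12·v_ref level, so flux-balance identities hold
to ~1e-10 relative in tests. Failure to converge raises an error naming
the species with the largest positive drift (e.g. a source flux
exceeding the summed drain capacity).

With equal source rates and the pABA-recycling side reaction, the
quantity **Q = [pABA] − [H2-HMPt] − [H2-HMPt-PP] is conserved** by the
dynamics. It is not a left null vector of the stoichiometric matrix — it
exists only because the two source rates are equal — so it is detected
numerically: left null vectors of the Jacobian at the initial guess
(fine-step central differences) are accepted as invariants only if they
also annihilate the Jacobian and the right-hand side at probe points
elsewhere in state space. Detected invariants are pinned to the caller's
guess during root finding, which makes the root and relaxation answers
agree and makes the solution unique. Every observable except the
pABA / H2-HMPt-PP split is independent of Q.

Local stability is assessed from the eigenvalues of a central
finite-difference Jacobian (step max(1e-8, 1e-4·|x|)). One eigenvalue
per conserved direction is ~0; `stable` means no eigenvalue has a real
part above the neutral threshold (1e-7 of the spectral radius), with the
count of neutral modes reported alongside the number of detected
invariants. On the default model the spectrum is one neutral mode plus
six strictly decaying modes (slowest ≈ 2e-3 s⁻¹, the drain relaxation,
giving the ~10-minute folate-pool recovery timescale seen in the
overexpression simulations).

A corollary: the elasticity with respect to a *single* source flux is
undefined (perturbing one source alone removes the steady state);
sources must be scaled jointly through the scenario multiplier `f_reg`.
`local_sensitivity` reports this as an error rather than a number.

## Default parameters

No kinetic constants for this pathway are reliably transferable from
in vitro data, so the defaults are the package's own calibration,
chosen to put the wild-type steady state at physiologically sensible
values: total folate [THF]+[CH2-THF] ≈ 3e-5 M (~30 µM, with
THF:CH2-THF ≈ 2:1), [H2-HMPt] ≈ 1e-7 M, and a wild-type recycle flux
v_PanB ≈ 0.2·v_net. The source flux v_net = 1.66e-7 mmol·ml⁻¹·s⁻¹ is
the growth-dilution demand for THF compounds in exponentially growing
E. coli. Fixed pools use standard E. coli metabolome values (ATP 9.6 mM,
ADP 0.56 mM, AMP 0.28 mM, Pi 10 mM, PPi 0.5 mM, Ser 68 µM, Gly 3.7 mM);
the steady state is insensitive to all of them except Ser and Gly, which
act on the THF:CH2-THF ratio exactly as the GlyA rate constants do.

The two drains deliberately use different Km values (DRAIN_THF km =
1e-5, DRAIN_CH2THF km = 1e-4 M). A symmetric pair would be only jointly
identifiable from steady-state concentrations (GlyA pins the ratio, so
the data constrain essentially one total), and distinct saturation
regimes keep the drain parameter actually fitted in the recovery harness
well conditioned.

Scenario defaults: the PanB overexpression multiplier `f_panb` defaults
to 50. The measured mRNA induction spans 500–6000-fold, but the
effective enzyme-level multiplier is unknown; every qualitative property
asserted in the tests (initial CH2-THF dip, H2-HMPt rise, folate
recovery bounded by wild type) holds for any multiplier > 1 in the
stable regime and is exercised at 5, 50 and 500. The regulation
multiplier `f_reg` is never hard-coded: it is fitted by
`fit_regulation_multiplier` so that total folate rises by a target
fraction (46% by default, the observed increase under PanB
overexpression). With default parameters the fitted value is
f_reg ≈ 1.174. At very large `f_panb` (~500) the GlyA disequilibrium
shift moves the post-induction total folate slightly (~0.5%) above the
wild-type value; the "recovery does not exceed wild type" property is
therefore asserted with a 1% tolerance.

## Sensitivity analysis

`local_sensitivity` computes scaled (elasticity-style) coefficients
d ln m / d ln p by central log-log differences, each evaluation a fresh
steady-state solve; the default perturbation is ±5%, and halving it
moves smooth coefficients by far less than 10%. Fixed-pool
concentrations can be scanned with the `("species", id)` parameter
form. The headline structural results: the pathway flux is pinned at
v_net + v_PanB regardless of the FolK/FolP/FolC/FolA constants
(elasticities ~1e-12 numerically, tested across a 100-fold range); GlyA
kf and kr have elasticity ±1 on the THF:CH2-THF ratio; the drain
parameters are the only controllers of total folate; the PanB constant
controls [H2-HMPt] and the recycle flux.

## Calibration

`fit_wildtype` minimizes a weighted sum of squared log residuals of
steady-state observables (concentrations span orders of magnitude, so
the log scale equalizes target influence) with bounded trust-region
least squares; up to 10 seeded log-uniform multi-starts are tried if the
first start fails. Convergence requires every |log residual| < 0.25
(targets matched within ~28%, inside typical replicate scatter); an
infeasible target — e.g. a total drain flux different from v_net, which
moiety conservation forbids — raises an error carrying the best result.
`identifiability_report` profiles each fitted parameter over a ±10-fold
range and flags flat profiles (e.g. any upstream constant when only
fluxes are targeted).

`fit_regulation_multiplier` is a bracketed scalar root solve (Brent) on
the strictly increasing map f_reg ↦ total-folate fold; the achieved fold
matches the target to ~1e-10 relative, and the reachable fold is bounded
by the summed drain capacity.

## Synthetic data

`generate_measurements` emulates replicate steady-state HPLC-style
measurements: for each (scenario, observable) the true steady-state
value is multiplied by mean-preserving lognormal deviates with a stated
CV (default 0.1, 3 replicates). All randomness flows from one seed and
regeneration is bit-identical. What the generator does *not* emulate:
extraction/oxidation chemistry, cell lysis leakage, interconversion of
folate forms during workup, or correlated (batch) error structure —
so passing recovery tests demonstrate the calibration machinery, not
robustness to real measurement pathologies.

The recovery harness fits {DRAIN_THF.vmax, GlyA.kf, PanB_side.k} to
wild-type + overexpression targets of {[H2-HMPt], [THF], [CH2-THF]};
each is directly identified by that target set (total folate, folate
ratio, and the overexpressed H2-HMPt level respectively). Noiseless
recovery is exact to optimizer precision (<1e-12 log error); at CV 0.1
with 3 replicates the seeded check requires <15% log error. The noise
propagation puts typical errors at 3–7%; across 20 seeds the worst case
observed was ~16%, i.e. a ~2.8σ draw can graze the bound, which is why
the check is a seeded stochastic tolerance rather than a universal one.

## Neighborhood classification

A folK gene is panB-clustered (resp. folB-clustered, both, neither)
according to whether the nearest panB / folB on the same replicon lies
within a window of coding sequences. Distance is the difference of CDS
ordinals (0-based, in coordinate order per replicon), not base pairs;
the window (default 10) is inclusive; strand is ignored; replicons are
linear unless flagged circular, in which case distance wraps the short
way. GFF3 input is parsed with gffutils (CDS features, labels from a
configurable attribute key, case-insensitive), and a shuffled file
yields the same ordinals as a sorted one; a TSV gene table (genome,
replicon, ordinal, gene, strand) is accepted as a lighter alternative.
Gene identity comes from annotation labels only — no homology search.

## Problem sizes and numerical checks

The test suite and the acceptance script run the 7-species ODE system,
toy one-species models with closed-form steady states (the Monod-drain
oracle: [X]ss = km·v0/(vmax−v0), elasticity vmax/(vmax−v0)), recovery
fits with 6 targets × 3 replicates, and brute-force-enumerable toy
replicons of ~25–60 genes; the whole suite completes in a few seconds.
Integration defaults are rtol 1e-8 / atol 1e-12 (LSODA); trajectory
output clips concentrations within 100·atol of zero.

## Known limitations

- Only THF and CH2-THF are modeled as folates; measured "total folate"
  in cells includes 5-methyl-, formyl- and methenyl- forms that the
  model lumps into its two species.
- Regulation is phenomenological (an exogenous source-flux multiplier),
  not a mechanistic transcription model.
- The steady-state manifold direction (the pABA / H2-HMPt-PP split) is
  fixed by initial conditions, not by data; no observable in the
  calibration set constrains it.
- Local sensitivity only; no global (Sobol/Morris) screening, no
  bifurcation analysis, no stochastic kinetics.
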