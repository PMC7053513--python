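# Methods

## Scope and model

`osmoflux` performs stationary ¹³C metabolic flux analysis (MFA) for
*Bacillus megaterium* growing on glucose, with the specific goal of
quantifying the osmotic-stress rerouting of carbon toward proline and
poly-3-hydroxybutyrate (PHB). The shipped reaction model
(`data/bmegaterium_model.csv`) is a curated reconstruction of the central
pathways: PTS uptake, glycolysis, oxidative and non-oxidative pentose
phosphate pathway (transketolase ×2, transaldolase), the full TCA cycle,
both anaplerotic carboxylases (PepC and PycA), pyruvate oxidase (Pox) and
the Pta–AckA acetate route, lactate dehydrogenase, secretion of acetate,
lactate, pyruvate, succinate and 2-oxoglutarate, net glutamate synthesis
(GS/GOGAT lumped), the osmo-responsive proline branch (glutamate-5-kinase +
glutamate-5-semialdehyde dehydrogenase lumped, spontaneous cyclization,
pyrroline-5-carboxylate reductase), and the PHB branch (PhaA condensation,
PhaB reduction, PhaC polymerization as the drain). Malic enzyme and the
glyoxylate shunt are excluded; acetate is secretion-only (no re-uptake);
there is no transhydrogenase, so NADPH and NADH pools are strictly
separate and "NADPH excess" is well defined. The reaction list itself is a
documented reconstruction, not a published table; it is the smallest model
consistent with the pathways named above.

Atom maps use 1-based conventional carbon numbering. Succinate and
fumarate are symmetric: their reactions carry two equally weighted mapping
orientations, which is exactly how molecular symmetry scrambles label.
CO₂ is an explicit 1-carbon balanced metabolite (decarboxylations feed it,
PepC/PycA fix it, an outflow closes it), so carbon conservation holds
atom-by-atom in every reaction — asserted at load — and CO₂ release equals
carbon-balance closure by construction.

Isocitrate dehydrogenase is modeled NADP-dependent (as in bacilli), making
the oxidative PPP (Zwf + Gnd) and Icd the NADPH sources.

## Labeling simulation

The forward model uses the elementary-metabolite-unit decomposition: the
minimal set of carbon-atom subsets reachable backwards from the measured
fragments, solved size-by-size as linear systems; condensations convolve
smaller EMU mass distributions. A full-isotopomer fixed-point simulator
(2ⁿ states per metabolite) lives in the test suite as an independent
oracle; EMU and enumeration agree to <1e-10 on toy networks with cleavage,
condensation, reversibility and symmetric scrambling.

Reversible reactions enter as bidirectional rates v_fwd = max(v,0)+v_exch,
v_bwd = max(−v,0)+v_exch. For fitting, exchanges are parametrized as
ξ = v_exch/(uptake + v_exch) ∈ [0, 0.99], bounding the optimizer's domain
while allowing near-complete equilibration (v_exch up to 99× the uptake).

Measured amino acids map to precursor EMUs by the standard biosynthetic
atom assignments (alanine ← pyruvate; valine ← 2 pyruvate; leucine ←
acetyl-CoA + 2 pyruvate; isoleucine ← oxaloacetate + pyruvate;
serine/glycine ← 3-phosphoglycerate; aspartate/threonine ← oxaloacetate;
glutamate/proline ← 2-oxoglutarate via the explicit glutamate node;
phenylalanine/tyrosine ← 2 PEP + erythrose-4-phosphate). A fragment built
from several precursor molecules has the convolution of their EMU MIDs.
Which fragments enter a fit is a panel choice: the default TBDMS panel
([M-57] = all backbone carbons, [M-159] = backbone minus C1) covers Ala,
Gly, Val, Leu, Ile, Ser, Thr, Asp, Glu, Phe, Tyr, Pro; Gln/Asn pool into
Glu/Asp under the acid hydrolysis of biomass protein, Cys and Trp are
hydrolysis-labile and excluded.

## Natural-isotope correction

Correction matrices are built per fragment from pinned isotope abundances
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205,
²⁹Si 0.04685, ³⁰Si 0.03092, ³³S 0.0076, ³⁴S 0.0429;
`data/isotopes.csv`). Column j is the mass-shift distribution of the
derivatization shell convolved with the (n_backbone − j) unlabeled backbone
carbons at natural ¹³C; a flag can exclude the backbone term (both
correction-matrix conventions exist in the literature; backbone-included is
the default). Correction solves C·x ≈ raw by non-negative least squares and
renormalizes, which is robust to truncated mass windows (4 masses beyond
M+n are recorded by default); measured σ propagate through the linearized
pseudo-inverse. The round trip uncorrect→correct is exact to <1e-6 for
every panel fragment.

## Flux estimation

Hard equality constraints — uptake ≡ 100, biomass precursor drains, and the
conventionally fixed PycA and Pox fluxes (below) — are eliminated by
Gaussian elimination into an affine free-flux basis; measured secretion
rates stay in the objective as weighted residuals. The weighted SSR over
all tracer experiments (summed jointly; per-experiment residuals are
available on the result) is minimized by scipy's bounded trust-region
reflective least squares from 20 random feasible starts by default,
seeded and reproducible; restart outcomes are recorded. A σ floor of 0.003
mol-fraction guards against vanishing reported MID σ (typical GC-MS
precision). Dependent irreversible fluxes are kept non-negative by penalty
residuals; iterates that still reach a singular EMU system (a zero-flux
dead end) degrade to a constant measurement block so the penalties can pull
the optimizer back.

Degrees of freedom count each normalized MID of length k as k−1
independent entries (the simplex constraint removes one) plus one per rate,
minus the fitted parameters. On noise-consistent synthetic data the
minimized SSR is χ²-distributed with these dof (KS-tested in the suite)
and single fits land inside the central 95 % χ² band.

Monte-Carlo confidence intervals resample every MID entry and rate with
its own σ (MIDs clipped at 0 and renormalized), refit from the point
estimate, and take 2.5/97.5 percentiles; n = 200 by default (a compromise
between percentile stability and desk-scale runtime), with failures above
20 % reported as an error. Empirical coverage on an identifiable toy is
~93 % over 200 replicates.

Two structural non-identifiabilities of this network are handled by
convention: with PEP and pyruvate carrying identical carbon skeletons, the
PepC/PycA split is invisible to amino-acid labeling, and since Pox acetate
and Pta acetate inherit the same C2 unit, the Pox/Pta split is likewise
flat in the objective. Both reactions are therefore `constrained` in the
shipped model and fixed to small conventional values (PycA 2 %, Pox 5 % of
uptake) in the default scenario; freeing them is possible and the fitter
flags the resulting flat directions via an SVD of the jacobian.

## Synthetic data (what it emulates, what it does not)

The generator defines the study conditions. Growth parameters (μ, Y_X/S,
q_s) and secretion yields per NaCl molarity come from the shipped printed
physiology table; biomass precursor demands per condition
(`data/biomass_composition.csv`) are a reconstruction anchored at 0, 0.6
and 1.2 M — protein/RNA demands shrinking and proline + PHB demands rising
with salt, PHB at 6 %, 14.4 % and 29.5 % of cell dry weight — and are
piecewise-linearly interpolated for other molarities (constant beyond the
anchors, with a warning). Demand fluxes scale by μ/q_s into % of uptake.
The remaining free flux, the oxidative PPP split, is set by the synthetic
convention zwf = 22, 35, 60 % at 0, 0.6, 1.2 M — qualitatively the reported
rise, deliberately not anyone's fitted values. Tracer experiments are
99 % 1-¹³C glucose (modeled as a 0.99/0.01 two-component mixture) and
50 % U-¹²C/50 % U-¹³C glucose. Skeleton MIDs are pushed through the
fragment correction matrices to raw mass space, perturbed by additive
Gaussian noise (sd 0.005 mol-fraction, matching how MID σ are reported and
weighted; not Dirichlet), clipped at zero and renormalized; rates get 3 %
multiplicative noise. Growth curves are exponential with multiplicative
observation noise.

Passing the closure tests therefore shows the estimator inverts its own
forward model under realistic noise and identifiability structure. It does
not validate the reconstruction choices against the organism: real data
bring fragment-specific σ structure, drift, imperfect derivatization,
inaccurate biomass compositions and model misspecification that the
generator does not emulate. The published fitted flux maps, the 87 % NADPH
excess and the ~70 % CO₂ increase are not reproduction targets here: they
require the study's unpublished raw MID measurements.

## Cofactor ledger

Supply and demand per cofactor are signed flux-weighted sums of the
reaction coefficients; the NADPH demand additionally charges each biomass
drain with a per-precursor biosynthetic NADPH cost
(`data/nadph_costs.csv`), a coarse reconstruction chosen to be
redox-plausible under the carbon-tight measured physiology (the heavy
acetate overflow at 0 M caps the feasible PPP share, hence total NADPH
turnover). A flag restricts the demand side to growth biomass only,
excluding the explicit pathway consumers. With the synthetic conventions
the NADPH balance moves from a small deficit at 0 M to a ~47 % excess at
1.2 M — the qualitative trend that accompanies PHB accumulation; the
magnitudes are properties of the reconstruction, not measurements. The
adenylate energy charge is Atkinson's (ATP + ½ADP)/(ATP+ADP+AMP).

## Physiology

μ is the least-squares slope of ln(biomass) over an explicitly chosen
exponential window (no automatic phase detection); yields are concentration
differences over the window; q_s = 1000·μ/Y_X/S assumes balanced
exponential growth. Fold changes round half-up to one decimal because
printed one-decimal folds are produced that way (62.6/5.8 = 10.793 → 10.8).
The printed table's own inconsistencies (a "~40 %" yield-drop statement vs
29.4 % from the table values; a 13.4-fold oxoglutarate statement vs 6.1
from the table) are noted and left unresolved; neither is computed by this
package.

## Numerical choices and problem sizes

Rank and basis tolerances 1e-9 on row-normalized systems; EMU systems are
dense solves (the shipped decomposition has ~200 EMUs across sizes 1–5);
convolution is explicit (it is also the tested primitive). Optimizer
tolerances ftol = xtol = 1e-10. The calibration studies in the test suite
use 200 replicates with 100 Monte-Carlo samples each on a two-route toy,
and the shipped-model inverse problem uses 8 restarts on one seeded noise
realization — sizes chosen to keep the full suite at desk scale while
leaving the statistical checks meaningful.
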