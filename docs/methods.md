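# Methods

## The pathway model

The simulator tracks the SAM transmethylation pathway, its transsulfuration
and polyamine branches, and the adenylate/adenosine recycling system of a
hemocyte as a well-mixed reaction network with first-order mass-action
kinetics: each reaction's rate is a capacity constant (min⁻¹ per amount
unit) times the product of its rate pools' total amounts. Two saturating
terms are the only departures from pure first-order kinetics, and both are
textbook product inhibitions that the model needs to reach bounded steady
states under knockdown: SAH inhibits the lumped methyltransferase
(rate ∝ 1/(1+[SAH]/K_i), K_i = 0.2 a.u.) and SAM inhibits its own
synthesis by SAM synthetase (K_i = 1.0 a.u.). Amounts are arbitrary
concentration units; nothing downstream depends on their absolute scale,
only on ratios and fractions.

### Label bookkeeping

Isotope labels are tracked at *moiety* resolution rather than as positional
isotopomers. Three carbon units move through this pathway as intact blocks:
the methyl carbon of methionine (1 C), the homocysteinyl backbone (4 C) and
the adenosyl group (5 C). A pool with *k* of these moieties has 2^k
labeling states; reactions copy labels from substrate moieties to product
moieties, preserving the joint distribution of moieties that travel
together (so the m+4 methionine impurity — backbone labeled, methyl not —
stays an m+4 species through SAM and SAH instead of being scrambled) and
treating distinct substrates as independent. This is exactly enough
resolution to reproduce every mass-shift class an LC-MS isotopologue
readout of this pathway shows: Met m+4/m+5, SAM m+4/m+5 (methionine
carbons) or m+5 (adenosyl), SAH/CTH m+4, MTA m+1, and m+5 for the
nucleotide pools under the adenosine tracer.

The Met-¹³C₅ stock carries a 3% m+4 impurity whose methyl carbon is the
unlabeled one — the same species that remethylation of labeled
homocysteine would produce, which is what makes the impurity the detection
floor for the remethylation test. For adenosine-¹³C₅ the adenosyl moiety is
a single 5-carbon unit, so a "one label short" impurity is not
representable; that fraction of the stock enters as unlabeled instead, and
Ado-tracer pools acquire m+5 only.

### Conditions, integration and measurement

A scenario is (genotype, infection, tracer, nutrient supply). Infection
scales methyltransferase, SAM synthetase, methionine transport (uptake and
efflux together — the L-type transporters are exchangers), de novo purine
synthesis, ADP→ATP regeneration, and the inducible shares of adenosine
kinase (Adk3-like, on top of a constitutive Adk2-like share) and adenylate
kinase (Ak1-like vs Ak2-like). RNAi multiplies exactly the targeted
enzyme's capacity (for Adk3/Ak1, only the inducible share) by the
knockdown factor, default 0.1. The nutrient-supply scalar in (0, 1] scales
ADP→ATP regeneration only; lowering it starves the recycling arm, so the
exported share of adenosine rises strictly while the Ado→AMP share falls —
the model's encoding of the activity/nutrient-balance sensor idea.
Remethylation of homocysteine and the Ahcy-independent Met→CTH bypass
exist as reactions but default to zero capacity.

Each condition is first pre-equilibrated unlabeled for 1200 min (RK4, step
0.5 min) so the cells enter the assay at their own quasi-steady metabolite
levels — knockdowns and the ~20 h of post-infection history live in the
initial state, not in the 20-minute assay. The labeled incubation then
runs 20 min with a fixed-step classical RK4 at 0.01 min; halving the step
changes endpoint fractions by <1e-6, and in a closed variant the labeled
methyl- and adenosyl-moiety totals are conserved to solver tolerance. A
vectorized exact Gillespie simulation of a small unary chain serves as an
independent stochastic oracle in the tests.

### Calibration

Ten-odd capacity constants and six infection scales were tuned by
coordinate search against the study conditions and frozen as a versioned
fixture (`samtrace/data/default_capacities.yaml`): ~70% labeled
intracellular methionine in resting cells and ≥80% in activated cells
after 20 min of Met-¹³C₅; a two-fold infected/uninfected SAM level ratio
(SAH lands at ~1.7×); an endpoint SAM m+5 : ATP m+5 ratio of ~0.13 under
Ado-¹³C₅ in activated cells; SAH accumulation and a collapsed methylation
index under Ahcy knockdown; and a blunted infected AMP rise under Adk3
knockdown. Two calibration compromises are worth knowing about: the
infection-induced rise in exported adenosine+inosine is *attenuated* to
less than half of control's under Ahcy-RNAi rather than fully abolished
(with these kinetics the quasi-steady knockdown flux scales like the
square root of its input, so a residual rise survives), and the infected
ATP m+5 fraction comes out slightly above the uninfected one whereas real
activated hemocytes dilute it below — the model has no compartmentalized
ATP pool to channel recycled adenosyl preferentially into SAM.

### Measurement model

Peak tables map endpoint pool amounts × class fractions to areas through
per-metabolite response factors. Noise is one multiplicative log-normal
draw per sample × metabolite (default log-sd 0.15) shared across that
metabolite's isotopologue classes: extraction and instrument response vary
per compound, while coeluting isotopologues keep their ratios. All
randomness sits behind one explicit seed; sd 0 makes emission
bit-identical. Homocysteine is emitted flagged non-detected. Supernatant
tables report exported adenosine with a configurable 0.5 : 0.5
adenosine:inosine split for the residual extracellular deaminase activity
that persists under EHNA inhibition.

## The cohort generator

Pupation times are normal around an arm median (dispersion 8 h), with the
median additive in a baseline (118 h AEL), a genotype-wide developmental
shift (−2 h for Ahcy-RNAi, both arms) and an infection delay (10 h
control, 4 h Ahcy-RNAi, 7 h Adk3-RNAi, 6 h Ak1-RNAi). Larvae are censused
on a grid (default 1 h; the 6 h field census is available but cannot
resolve the 2 h genotype shift), right-censored at the observation end if
they never pupate, and carry Bernoulli adult-survival and melanized-egg
flags (10% of infected adults lack an egg and are excluded from survival
denominators) plus negative-binomial lamellocyte counts. The delay readout
is the t50 estimator: the difference between arms in interpolated time to
50% of each arm's *own* final pupation fraction, with a seeded
percentile bootstrap (1000 resamples over larvae) for the CI. Log-rank
comparisons treat pupation as the event.

## What the synthetic data do and do not show

The generator encodes the pathway topology, the label classes, the
direction and rough size of every perturbation the analyses are tested
against, and realistic measurement noise. It does not emulate positional
isotopomer effects, natural-abundance isotopes (none are modeled, and no
correction is applied anywhere), chromatographic artifacts, biological
replicate-to-replicate variation beyond the log-normal response term,
compartmentalization, or RNA-degradation adenosine sources. Tests passing
on these data therefore demonstrate that the estimators recover what the
generator put in under the stated noise — not that the biological
conclusions would survive instrument-specific systematics.

## Statistical conventions

Two-group comparisons use the unpaired equal-variance *t* test; three or
more groups use ordinary one-way ANOVA with Tukey's pairwise adjustment;
stars bucket at 0.05/0.01/0.001/0.0001. Both tests are Monte-Carlo
calibrated in the acceptance suite (type-I/family-wise error ≈0.05 over
10⁴ null simulations), as is the log-rank test. The remethylation verdict
is a single pre-specified strict inequality against the medium impurity
statistic measured in the same run, with no multiplicity correction. TPM
carries no gene-length term by default (3′-end tag libraries yield one tag
per transcript); a length-aware mode exists for conventional libraries.
The ΔΔCt calibrator is aggregated by arithmetic mean over its replicates.
The 4-fluorophenylalanine extraction standard is excluded from the
normalization panel, and the panel keeps only metabolites with an m+0
measurement in every sample.

## Problem sizes

Defaults were chosen so a full analysis runs on a laptop: tracer
simulations integrate ~40 state variables for 1200 + 20 model minutes in
about two seconds; delay recovery uses n = 250 larvae per arm averaged
over 25 seeds; the Monte-Carlo test calibrations use 10⁴ null
simulations at 30 larvae (log-rank) or 3 × 10 observations (Tukey).
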