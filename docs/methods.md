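# Methods

## Trial design and response model

A *case* is one patient-derived model tested in replicate mice (default 3 per
arm; vehicle and treatment arms).  Tumor volume follows the caliper formula
TV = ½·w²·l with the shorter axis squared; the axes are canonicalized so the
formula is symmetric.  The case-level response is the **mean of per-mouse
percent changes** at the evaluation day (default day 21), not the percent
change of mean volumes; the vehicle arm is carried for QC only.

Category cutoffs follow the mouse-adapted RECIST convention used in PCT
studies: mCR ≤ −95%, mPR ≤ −50%, mSD < +35%, mPD otherwise, with boundary
ties resolving to the better category.  All cutoffs are configurable
(`ResponseCutoffs`).

Relapse is the first measurement at which the volume exceeds the post-baseline
nadir by 73% (the volumetric analogue of a 20% diameter increase) **and** an
absolute floor of 50 mm³, confirmed by the following measurement, within a
90-day monitoring window.  An unconfirmed candidate on the final measurement
raises an insufficient-follow-up flag instead of a call.

The two-round decision tree applies, in order: early termination →
*unevaluable*; replicate round-1 categories spanning non-adjacent classes
(e.g. one mCR and one mPD mouse) → *individual differences*; round-1 mPD →
*intrinsic resistance*; no relapse through the monitoring window →
*sensitive*; relapse → second round, where mPD → *acquired resistance* and
mPR/mCR → *DTP*.  Two deliberately open points are resolved as follows:

- **Round-2 mSD** has no defined fate in the workflow; such cases are
  returned as `indeterminate` with a flag rather than guessed into a group.
- **Non-relapsing round-1 mPR/mSD** cases are labelled *sensitive* (the tumor
  was controlled and never regrew) with an explanatory flag; the workflow
  only specifies the mCR branch explicitly, and any durably controlled tumor
  is operationally sensitive.
- Day-21 change (nearest measurement within a ±3.5-day window) is the default
  evaluation; best-response-within-window is intentionally not the default.

Cohort percentages are reported to two decimals, rounded half-up, so printed
tallies recompose exactly.  Waterfall values are clamped to [−100%, +200%];
the representative value per case is the round-2 change when a second round
exists, else the round-1 change.

## CCF estimation and subclone clustering

For a variant with allele fraction VAF, sample purity ρ, tumor/normal copy
numbers CN_t/CN_n, the multiplicity is m = clamp(round(VAF·(ρ·CN_t +
(1−ρ)·CN_n)/ρ), 1, CN_t) and the CCF is the same pre-rounding quantity
divided by m, clipped to [0, 1] with the pre-clip value retained and logged —
clipping is never silent.  Variants with alt reads at a CN 0 locus are
excluded with a log entry.

Subclones are inferred with a **finite binomial mixture**: cluster k has one
prevalence parameter per timepoint, and variant i's success probability at
timepoint t is φ_kt · ρ·m_i/(ρ·CN_t,i + (1−ρ)·CN_n,i).  EM with spread
(k-means++-style) seeding and multiple restarts (default 20) maximizes the
likelihood; the per-iteration log-likelihood is checked for monotone ascent
and exposed in the model report.  The M-step has a closed form when all
variants share the VAF→CCF factor and otherwise solves the (strictly
monotone) score equation by bracketed root finding.  K is selected by BIC
over 1..K_max (default 10) with parameter count K·T + (K−1).  This is a
deliberately lightweight stand-in for Dirichlet-process clustering tools such
as PyClone; the fate logic accepts externally computed cluster assignments,
so any subclone caller can be substituted.

Fates compare pre- vs post-treatment prevalence against a presence threshold
(default 1%): appearing → *newly generated*, vanishing → *eliminated*,
otherwise *persistent* with the direction taken from the change in percentage
points against a ±2.0 pp stable band (so 26%→23% is decreasing and 27%→27%
stable).  An intermediate on-treatment timepoint is carried in the track but
does not define the fate.

Gene-set over-representation uses the one-sided hypergeometric tail with
Benjamini–Hochberg adjustment across sets; zero-overlap sets report p = 1.

## Trajectories

Clone trees are inputs (edge-list TSV or annotated Newick); no tree inference
is performed, and no joint re-estimation across patients (as transfer-learning
tools like REVOLVER do) is attempted — recurrence counting here is purely
descriptive.  Each driver-bearing clone emits one event; drivers co-occurring
in a clone are rendered as an unordered `A/B` co-event, never given an
invented internal order.  Maximal GL-to-leaf driver paths are deduplicated in
label space (a path that is a proper prefix of another is dropped, since
distinct clones may carry identical driver labels).  A trajectory is
*repeated* when ≥ min_support (default 2) distinct cases at the same
timepoint carry it.  An event is counted *clonal* when its clone lies on the
unbranched chain from the root, *subclonal* otherwise.  Pre/post repeated
sets are compared per family (keyed by the first post-GL driver) through an
ordered cascade — disappeared, newborn, unchanged, truncated-to-early,
extended, divergent-extension — which is mutually exclusive and exhaustive by
construction.

## Biomarkers

AUC is the Mann–Whitney U statistic over n_A·n_B pairs with midrank tie
handling, oriented as P(resistant > sensitive) + ½P(tie); the predictive flag
is AUC > 0.80 and no multiple-testing correction is applied to the screen
(the Fisher tests on alteration frequencies carry a clearly labelled,
beyond-protocol BH column).  Cross-platform validation is represented as two
independent screens and an intersection report, with no cross-platform
normalization.  Trend calls over ordered timepoints require rises in
≥ min_support (default 2) consecutive intervals with no fall beyond a
tolerance (default 0, strict monotone); the published "in at least two
samples" phrasing is mapped to interval support as a documented
interpretation.

## Dose-response and synergy

Viability curves are normalized to fractional inhibition anchored at the
zero-dose wells and fit with E(d) = fmax/(1+(EC50/d)^h) by bounded least
squares from a multi-start grid (7 log-spaced EC50 starts × h ∈ {0.5, 1, 2}).
The IC50 is the dose of 50% absolute inhibition; when the fitted curve does
not reach it within the tested range the fit is **censored** and the maximum
tested dose is reported as a lower bound.  Near-constant curves (span < 2% of
the inhibition scale) are flagged flat with undefined EC50.

The combination index is the canonical Loewe sum CI = d₁/D_x,1 + d₂/D_x,2 at
a common effect level x (default 0.5); censored single-agent doses propagate
as CI **upper bounds**, never point estimates.  Calls: CI < 0.75 synergistic,
CI > 1.5 antagonistic, otherwise additive (boundaries additive).  On a dose
matrix the marginals are Hill-fit from the zero-dose row/column, and each
interior combination is interpolated along its (i−1, j−1) grid diagonal —
which preserves the dose ratio under serial dilution — log-linearly in dose
to the requested effect level; each crossing is reported once, at the
bracketing cell.  Grids where no combination reaches the level return an
empty CI list with an explanatory note.

## Synthetic data

The generator exists so every stage has ground truth.  Per-clone active (A)
and persister (P) volumes follow

    dA_k/dt = g_k·A_k·(1 − V/Vmax) − s_k·c(t)·A_k − q_in,k·[c>0]·A_k + q_out,k·[c=0]·P_k
    dP_k/dt = q_in,k·[c>0]·A_k − q_out,k·[c=0]·P_k

integrated with fixed-step RK4 (dt = 0.25 d; rates ≤ 0.6/d make this accurate
to ~1e−8 relative while keeping 200-case suites fast).  Logistic growth with
multiplicative kill is the simplest law producing regression, stasis, relapse
and persister phenotypes.  Clones below 0.5 mm³ are eradicated (an extinction
cutoff standing in for the discreteness of small cell populations).  Defaults:
V₀ = 200 mm³, Vmax = 4000 mm³, twice-weekly measurements, drug on days 0–21,
monitoring to day 90, measurement noise lognormal with scale 0.10, per-mouse
rate jitter 0.05.  The archetype mix defaults to the discovery-cohort
distribution (21/9/8/4/4/3 of 49).

Archetype parameterizations: sensitive (g = 0.08/d, s = 0.5/d → eradication
by ~day 15), intrinsic (s = 0.02 → progression), acquired (sensitive major
clone + 1% resistant subclone at g = 0.09 → mPR, relapse near day 36–38,
round-2 mPD), dtp (persister entry 0.15/d under drug, exit 0.2/d off drug →
mPR, persister-driven relapse, round-2 mPR).  The individual-differences
archetype *constructs* per-mouse kill-rate heterogeneity (multipliers 1.0,
0.0, 0.1 across the replicate mice) rather than drawing from a wide jitter
distribution — three i.i.d. draws would often agree by chance, which is not
what that group describes.  Round 2 is seeded by passaging the clone
composition at the (noise-free, case-level) relapse day back to V₀.

Variant tables draw alt reads Binomial(depth, VAF) with VAF =
CCF·ρ·m/(ρ·CN_t+(1−ρ)·CN_n); a mutation's CCF sums its clone's subtree, so
trunk mutations are inherited.  Expression is Gaussian on the log scale with
planted markers shifted by a chosen effect size in the resistant group.  Dose
matrices solve the Loewe equation d₁/D(f) + d₂/D(f) = α by bisection per
cell, with α = 1 additive and a synergy factor α < 1 pulling isoboles inward;
single-agent margins always follow their exact Hill curves.

All randomness descends from one integer seed through per-case and per-assay
child streams, so identical configurations are bit-identical and subsets are
reproducible.

**What the simulation does not emulate:** measurement-schedule irregularity,
inter-mouse engraftment failure, immune or spatial effects,
pharmacokinetics beyond constant exposure, sequencing artefacts beyond
binomial sampling, and real co-expression structure.  Passing recovery tests
therefore demonstrates the *logic* of the pipeline under its own generative
assumptions, not performance on real PDX data.

## Numerical choices and limitations

- Percentages: decimal half-up rounding at 2 dp, matching how cohort tables
  are conventionally printed.
- EM ascent is asserted with a relative tolerance of 1e−6; BIC ties break
  toward the first (smaller) K.
- Hill fits bound fmax ∈ [0, 1.2], h ∈ [0.05, 10], log-EC50 within ±6 nats of
  the tested dose range.
- Test and recovery suites run at reduced scale (200-case cohorts, depth 500,
  50 variants per planted cluster) — sizes chosen to make the statistical
  assertions sharp while the full suite stays fast on one CPU.
- The CCF transform is the standard purity/copy-number one and can differ
  numerically from Dirichlet-process prevalences on real data; frequencies
  are always per analyzed sample set.
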