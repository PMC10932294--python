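# Methods

## Differential-protein calling

Intensities are modelled as strictly positive where detected; a missing
entry means "not detected", never zero. The processing order is fixed:
per-run total-intensity normalization (every run rescaled to the mean
run total, preserving within-run ratios), peptide→protein rollup by
summation (a protein is absent in a run iff all its peptides are),
technical-replicate averaging per animal, then group statistics.

Fold change is the ratio of linear group means after replicate
averaging. The t-test is Welch's (unequal variance) on log₂
intensities by default; log transformation stabilizes the variance of
multiplicative intensity noise, and Welch avoids assuming equal group
variances. Student's test and raw-scale testing are config options.
Proteins detected in fewer than two animals in either group are not
tested (the t-test is undefined); proteins absent from one entire group
have no finite ratio and are assigned sentinel fold changes (100 =
absent from control, 0.1 = absent from the experimental group). Since
no p-value exists for them, sentinel proteins are DEP-flagged purely on
the presence filter and reported as a separate stratum rather than
silently merged with tested DEPs.

DEP thresholds (defaults): two-sided fold change |log₂ FC| ≥ log₂ 1.2,
BH-adjusted p < 0.1, and presence in ≥ 50 % of the overexpressing
group's technical runs. The fold-change rule is deliberately read as
two-sided (FC ≥ 1.2 or ≤ 1/1.2); the presence rule is expressed as a
fraction so designs other than 5 animals × 2 runs work unchanged.
BH adjustment is the standard step-up procedure (statsmodels) applied
across all tested proteins of a contrast.

Over-representation uses the exact hypergeometric upper tail: given a
universe of size M, an annotation set of size K (intersected with the
universe), and N selected proteins, p = P(X ≥ observed overlap) with
X ~ Hypergeom(M, K, N), BH-adjusted across sets.

## Flux balance analysis

The model is a plain stoichiometric LP: maximize the designated
biomass-maintenance flux subject to S·v = 0 and box bounds (solved with
scipy's HiGHS backend; feasibility tolerance 1e-9, comparisons at
1e-8). FBA optima are generically degenerate, so a second LP minimizes
Σ|v| with the objective pinned at its optimum; the reported vector is
therefore reproducible across solvers, and the secondary solve provably
preserves the objective (asserted to 1e-8 in the tests).

Expression constraints: a measured protein's linear fold change *f* is
anchored at the optimized solution. For each regulated reaction with
baseline flux v\*: if v\* > 0 the upper bound becomes f·v\* (lower
bound dropped to 0 if it would cross); if v\* < 0 the lower bound
becomes f·v\* (mirrored guard); reactions idle at baseline keep their
bounds. This is the minimal reading of "fold changes linked to the
bounds of the optimized solution" and is isolated in one function so
alternative mappings can be plugged in. When several proteins regulate
one reaction, a boolean gene–reaction rule is honoured with AND = min
and OR = max of the member fold changes (standard GPR convention);
without a rule the combination policy is configurable, defaulting to
the geometric mean. The dysregulated condition re-optimizes the same
objective under the perturbed bounds — the disease state is still
assumed to do the best it can within its altered capacities.

Metabolite production is Σ max(0, coefficient × flux) over reactions
(consumption analogously on the negative part); the percent reduction
between conditions is reported at full precision and truncated to an
integer percent. Compartments follow BiGG-style id suffixes (`_c`
cytosol, `_m` mitochondrion, `_i` inner mitochondrial membrane); the
inner-membrane proton is `h_i` by default and configurable for real
models whose ids differ.

Model I/O: BiGG-schema JSON (round-trippable through cobrapy, which the
test suite uses as an independent LP oracle on the toy models) and a
native one-reaction-per-line TSV (id, equation string, bounds,
regulating proteins, objective flag).

## Network centrality ranking

Edges at combined confidence ≤ 0.7 are discarded (strict inequality),
duplicates collapse to the maximum confidence, self-loops are dropped.
STRING's 0–1000 integer score scale is auto-detected and rescaled.

Centralities are computed per connected component: degree (edge
count), betweenness (pair-fraction of geodesics through the node,
normalized by (n−1)(n−2)/2 within the component), closeness
((n−1)/Σ distances within the component), stress (raw geodesic count
through the node), eccentricity (max geodesic distance in the
component). Degree/betweenness/closeness/eccentricity are delegated to
networkx; stress, which networkx lacks, is computed from per-source BFS
distance and path-count matrices. All five are verified against an
exhaustive simple-path enumeration oracle on random graphs with ≤ 8
nodes.

The weighted score min–max normalizes each metric across nodes before
mixing — stress is an unbounded count while betweenness is a fraction,
so unnormalized mixing would let one metric dominate arbitrarily.
Eccentricity is inverted before normalization (peripheral nodes
contribute least); whether eccentricity should reward or penalize
centrality is genuinely open, so a config switch flips it. The default
weight vector (degree .28, stress .28, betweenness .20, closeness .14,
eccentricity .10) respects the intended importance ordering; the exact
values are configuration, not logic. Ties are broken lexicographically
by node id so rankings are total and reproducible. PageRank (damping
0.85, tolerance 1e-10) treats each undirected edge as walkable both
ways. Target selection removes nodes with |log₂ FC| < log₂ 1.5 before
taking the top-10 of the weighted and the PageRank orders, and reports
the union with provenance flags.

## EEG screening

Background amplitude is the median RMS over non-overlapping 10-s
windows — robust while bursts occupy under half the windows. Candidates
are runs of 1-s sliding-window RMS (0.1-s hop) at ≥ ratio × background,
merged across gaps < 1 s; they must last ≥ 5 s. The amplitude statistic
(windowed RMS rather than peak or envelope) is a documented choice and
configurable. "Evolution of amplitude and frequency" is operationalized
as a significant Spearman rank trend (p < 0.05) of windowed RMS or of
dominant spectral frequency (periodogram argmax) across the event.
Detection depends only on amplitude ratios, so it is invariant to
rescaling the trace. Because the original workflow included manual
proofreading by blinded experimenters, this module is a candidate
screener, not a validated seizure detector; rejected candidates are
logged with the criterion they failed. Multi-channel recordings are
screened per channel.

## Synthetic data

Intensity tables are multiplicative: log₂ intensity = protein baseline
(Normal(20, 1.5), typical label-free magnitudes) + planted group effect
+ biological noise (sd `noise_sd`, default 0.2) + technical noise (sd
`noise_sd`/4 — technical runs of one animal are far more alike than
different animals). Planted effects are exact in log₂ expectation;
dropout removes entries rather than zeroing them, so sentinel logic is
exercised. Defaults mirror the emulated study design: three groups,
five animals per group, two technical runs each. Reported intensity
noise magnitudes do not exist for the emulated study; 0.2 was chosen
once as a realistic label-free between-animal spread and doubles as the
condition under which DEP recovery is quantified.

Toy metabolic models have closed-form optima: a linear chain
(optimum = uptake capacity), a two-branch network (optimum = sum of
branch capacities), and an electron-transport-chain toy in which the
complex-III and complex-IV analogues pump 4 and 2 inner-membrane
protons per unit flux and ATP synthase consumes 3 per ATP, giving
optimum = 2 × capacity. Planted-hub graphs place non-hubs on a
high-confidence ring (degree 2) with low-confidence chords that the
0.7 filter removes, and attach each hub to half the non-hubs at high
confidence, guaranteeing hub degree ≥ 3× the median non-hub degree
after filtering. EEG traces are Gaussian background plus Tukey-tapered
linear chirps whose envelope RMS is the requested multiple of the
background (sine amplitude = ratio · σ · √2).

What passing the synthetic studies does **not** show: real LC–MS/MS
intensities have correlated, intensity-dependent missingness and
batch structure; real interaction networks are not ring-plus-hub; real
ictal EEG has spikes, artifacts and nonstationary background. The
recovery rates quantify internal correctness of the pipeline under its
own assumptions, not field performance.

## Problem sizes and determinism

Recovery experiments use 100 simulations/networks/traces each (200
proteins with 20 planted; 40-node networks with 2 hubs; 300-s traces at
200 Hz with two planted bursts), and the screened cohort uses 53
animals with 11 epileptic at 60 s / 128 Hz per trace — sizes at which
every experiment completes in well under a minute while estimating
rates to a few percent. All generators and experiments are pure
functions of their seed; the CLI threads one seed through every stage
and writes a manifest (inputs, parameter hash, version, seed) per run.

## Known limitations

* The fold-change→bound mapping is one of several defensible readings;
  genome-scale conclusions can be sensitive to it.
* Sentinel proteins carry no p-value; downstream counts should state
  whether the sentinel stratum is included.
* The LP returns one representative optimum; biologically distinct
  alternate optima are not enumerated (no flux-variability analysis).
* The evolution criterion is a rank-trend surrogate for expert visual
  assessment and inherits its p < 0.05 arbitrariness.
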