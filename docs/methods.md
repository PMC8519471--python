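# Methods

`tisopt` models the accessibility of mRNA translation-initiation regions and
exploits it for sequence design. This note documents the models, their
assumptions, the parameters that matter, and the design choices made where
the problem was genuinely open.

## Coordinates

All regions are anchored at the start codon: +1 is the first nucleotide of
the start codon, −1 the nucleotide immediately upstream, and 0 does not
exist. A region `start:end` is inclusive; its length is `end − start + 1`
when both ends share a sign and `end − start` otherwise (the missing
position 0). The equivalent `(i, l)` parametrisation — a sub-sequence of
length `l` whose last nucleotide sits at position `i` — is what the scan
grids use; for example `(24, 48)` is the region −24:24. Internally every
region maps to a zero-based half-open interval into the concatenated
`utr5 + cds + utr3` transcript, and a region that would need more flank than
the record provides is *undefined*, never silently truncated.

## Opening energy

The accessibility of a region is quantified as its opening energy,

    opening energy = −RT · ln(Z_unpaired / Z),

where `Z` is the partition function over all nested secondary structures and
`Z_unpaired` restricts the ensemble to structures in which every base of the
region is unpaired. The ratio is the ensemble probability that the region is
single-stranded; low opening energy means high accessibility. `RT` is the
thermal energy at the folding temperature (0.6163 kcal/mol at 37 °C). Unlike
a minimum-free-energy (MFE) calculation, which commits to one structure of
one excised window, the partition function is computed over windows that
extend well beyond the scored region, so sequence changes far outside the
region can still move its opening energy. `mfe_region` is provided as the
traditional comparison feature: the energy of the single most stable
structure of the excised window (−30:30 by convention).

Two engines implement the same adapter contract (the probability that the
stretch of exactly the region's length ending at the region's end is
unpaired):

* **production** — ViennaRNA's sliding-window algorithm (the RNAplfold
  computation) with Turner nearest-neighbour energies, window and maximum
  stretch `W = u = 210` nt by default. The window slides over the transcript
  and is constrained by the available flanks; flank truncation at transcript
  ends is the engine's documented behaviour and is not re-derived here.
* **toy** — an exact McCaskill-style O(n³) dynamic program over the *full*
  sequence under a deliberately non-physical model: a constant energy per
  Watson–Crick/GU pair (−1 kcal/mol by default) and a minimum hairpin loop
  of 3. Its sole purpose is to make the ensemble bookkeeping testable: a
  brute-force enumerator (`toy_partition_oracle`, guarded at 30 nt) lists
  every structure, cross-checks the structure count against an independent
  end-anchored recursion, and must agree with the dynamic program to 1e−9.
  The toy partition function is computed in plain float64; it overflows
  around ~450 nt and raises rather than returning garbage — toy-engine
  sequences are expected to be test-sized.

Numerical conventions: probabilities are clamped to (0, 1]; opening energies
are floored at 0 (a value of exactly 0 means no structure pairs any base of
the region); undefined scan cells are NaN.

## Synonymous-codon annealing

Finding the synonymous variant of a CDS with extremal opening energy is a
combinatorial search (about 3^N variants for N substitutable codons).
`anneal_opt` runs Metropolis–Hastings simulated annealing over codon space:

* **State space.** Codons 2..N+1 of the CDS (default N = 9; the start codon
  is immutable and the stop codon is never touched; N = None means the full
  CDS). Substitutions are always synonymous under the standard genetic code,
  so every visited sequence encodes the input protein.
* **Moves.** At temperature T, `m = max(1, round(T/T0 · R))` of the R
  degenerate replaceable codons are substituted, each to a uniformly chosen
  *different* synonym. The first move at `T = T0` therefore touches every
  replaceable codon and the final moves touch one — drastic to mild as the
  system cools.
* **Acceptance.** Standard Metropolis: improving moves always accepted,
  worsening moves with probability `exp(−ΔE/T)` where ΔE is the objective
  difference in kcal/mol. The objective is minimize (maximize accessibility),
  maximize, or `target` (rank by |energy − target|, used to tune expression
  to a chosen Expression Score rather than maximise it).
* **Schedule.** `T(k) = T0 · α^k` with `T0 = 1`, `α = 0.99`, stopping after
  `patience = 200` iterations without improvement or `max_iterations =
  1000`. The schedule shape (exponential cooling) is the modelled behaviour;
  the constants are this package's defaults and are exposed in
  `AnnealConfig`.
* **Chains and ranking.** Ten independent seeded chains run by default; each
  retains its best-so-far sequence, and the per-chain bests are
  deduplicated, motif-filtered and ranked by the objective (ties broken by
  substitution count, then lexicographically, so results are deterministic
  per seed).
* **Constraints.** Candidates that introduce a *new* forbidden-motif
  occurrence on either strand (defaults: AarI CACCTGC, BsaI GGTCTC, BsmBI
  CGTCTC) are rejected at proposal time, which keeps the chain on the
  constrained space instead of post-filtering solutions. Motif hits already
  present in the input (e.g. in a UTR or beyond the substitutable window)
  cannot be removed by synonymous changes in the window, so they are warned
  about rather than used to freeze the search. If no acceptable candidate
  can be proposed in 20 attempts the iteration is skipped, and if every
  chain's best violates the filter the input is returned with a warning.

`exhaustive_optimum` enumerates the full variant space (refusing beyond
50,000 variants) and serves as the ground-truth oracle in tests: annealing
must recover the enumerated optimum in ≥95% of small seeded instances.

Why only nine codons? Constraining substitutions to a short 5' window keeps
designs PCR-compatible and avoids the pathologies of full-length recoding,
while the opening-energy distributions achieved with a nine-codon window
stay close to full-length optimization (asserted in the tests as a small
Kolmogorov–Smirnov distance on scaled-down fixtures). Host presets give the
scored/optimised region: *E. coli* −24:24, *S. cerevisiae* −7:89,
*M. musculus* −8:11, generic "other" −24:89, or any custom region.

## Competing sequence features

`codon_features` implements the classical elongation-side metrics that
accessibility is compared against: CAI and tAI (geometric means of per-codon
relative-adaptiveness weights over the CDS, start and stop codons excluded
since their weights are fixed by definition), codon context (the same
construction over adjacent codon pairs, order-sensitive, terminal stop
dropped because sense-pair tables carry no stop pairs), global and local G+C
content, and the ncRNA-avoidance metric. For avoidance, the total
interaction energy between an mRNA and a non-coding RNA decomposes as
`ΔG_int = ΔG_u + ΔG_h` (opening plus hybridisation); the reported score is
the strongest (most negative) *hybridisation* component over the ncRNA set,
`(ΔG_h)_min`, between the mRNA region 1:30 and each ncRNA — the opening
term is deliberately excluded because accessibility is already scored
separately and would otherwise be double-weighted. The production
interaction engine shells out to RNAup (`-b -o`); a scripted stub engine
makes the min-selection logic testable without it.

The packaged weight tables (`data/*_synthetic.tsv`) are synthetic
stand-ins generated from a synthetic reference set so the feature code runs
out of the box; analyses that depend on real host weights should load their
own tables (`WeightTable.read_tsv`, or `WeightTable.from_codon_counts` for
the classical relative-adaptiveness construction from reference-gene codon
counts). The packaged 5-sequence ncRNA FASTA is likewise a synthetic
fixture, not a biological ncRNA set.

## Expression Score

Classification of expression success from opening energy uses the "less
than type" orientation: at threshold `t`, records with opening energy ≤ t
are called positive. From cumulative TP/FP/TN/FN counts the positive
likelihood ratio `PLR(t) = sensitivity / (1 − specificity)` is computed per
threshold, with percentile 95% bootstrap confidence intervals (10,000
record-level resamples by default; degenerate single-class resamples are
redrawn up to 10 times, then dropped with a warning — at realistic sizes
and prevalences redraws are never needed). Because the ratio is unstable
where cumulative TP or FP counts are small, thresholds with fewer than 5 of
either, and infinite ratios (FP = 0), are excluded from fitting (counts
logged in the diagnostics). A four-parameter logistic

    PLR_fit(x) = d + (a − d) / (1 + (x/c)^b)

is fitted to PLR against the opening-energy threshold by least squares with
multi-start initialisation (5 slopes × 3 midpoint quantiles, Levenberg–
Marquardt on (a, b, log c, d)); a constant-y input returns a flagged
degenerate fit. The fitted curve is monotone decreasing on x > 0 exactly
when `b(a − d) > 0`, which downstream monotonicity checks assert from the
fit rather than assume. Bayes' rule then turns a prior success probability
into a posterior:

    posterior odds = prior/(1 − prior) · PLR_fit(opening energy)
    Expression Score = 100 · posterior odds / (1 + posterior odds)

The default prior is 0.49, the historical proportion of expressed (21,046)
over cloned (42,774) constructs in large-scale expression campaigns; it is
configurable, including an "empirical" mode that uses the training
prevalence. A fitted likelihood ratio ≤ 0 is clamped to a small positive
floor with a warning. Scores are reported raw and rounded to the nearest
integer percent. `ks_distance` (two-sample Kolmogorov–Smirnov statistic)
compares opening-energy distributions between design strategies.

One caveat documented rather than hidden: the PLR at threshold `t`
conditions on the *cumulative* event "opening energy ≤ t", so the score
estimates P(success | OE ≤ t), not the pointwise P(success | OE = t). The
end-to-end recovery test therefore compares fitted scores against the
synthetic generator's cumulative posterior, obtained in closed form by
integrating its logistic label model.

## Synthetic labeled data

`labeled_fixture(n, seed, slope, midpoint, ...)` draws opening energies
uniformly on [2, 30] kcal/mol (the range the simulator also bins) and labels
each record Bernoulli with success probability
`p(x) = 1/(1 + exp(slope·(x − midpoint)))`, defaults slope 0.5 /mol·kcal⁻¹
and midpoint 12 kcal/mol — a decreasing logistic so lower opening energy
means likelier success, with slope 0 as the labels-independent degenerate
case. Generator parameters are recorded in the dataset metadata. What this
emulates is the *structure* of a success/failure expression campaign: a
monotone, noisy link between accessibility and outcome. What it does not
emulate: real campaigns' covariate structure (protein family, toxicity,
solubility), label noise from curation, non-uniform energy distributions,
or any sequence-level signal (energies are drawn, not folded). Passing
tests therefore demonstrate correctness of the estimators and pipeline, not
real-data effect sizes.

## Stochastic production simulation

`popsim` simulates recombinant protein production across constructs of
increasing opening energy. Constructs are bins of [2, 32) kcal/mol in steps
of 2 — 15 constructs whose nominal energies are the bin centers 3, 5, …, 31
— and each replicate run realises a jittered energy (Gaussian sd 1 kcal/mol,
truncated positive), modelling replicate variation and the gap between
estimated and in-vivo energies. Per iteration and per cell:

1. **Transcription.** A plasmid copy number is drawn uniformly in [30, 60]
   and each plasmid yields an mRNA with probability 0.5.
2. **Translation.** Each mRNA initiates with probability
   `1/(1 + exp((OE − 12)/2))` — a logistic gate at the 12 kcal/mol optimum
   (softness 2 kcal/mol), ≥ 1/2 at or below the optimum and occasionally
   allowing production from poorly accessible transcripts. Each initiation
   adds one protein and advances the molecule's translation counter.
3. **Decay.** Molecules translated more than 10 times decay with
   probability 0.5 per iteration.
4. **Growth and death.** Cells whose protein burden exceeds 10⁶ copies
   (toxicity; endogenous proteins are typically < 10⁴) die with probability
   0.4 per iteration; all cells face a small baseline death (5 × 10⁻⁵); a
   non-toxic cell divides on average once per 1,000 iterations with success
   probability 0.6 (death < reproduction: populations grow steadily).
   Newborn cells start with empty protein and mRNA pools.

Runs start from 100 cells and terminate after 10,000 iterations or
extinction; endpoint protein and cell totals are taken per construct, and
three replicate runs with independent random streams imitate biological
replicates. "Relative cellular fluorescence" is operationalised as endpoint
protein divided by endpoint cells. Population growth is unbounded in
expectation, so the implementation tracks a uniform sample of at most 150
cells together with a scale factor (subsample-and-rescale on overflow);
reported cell and protein totals are the scaled population values.

Parameter provenance, for honesty about what is modelled versus chosen: the
bins, plasmid range, 12 kcal/mol optimum, 10-translation decay rule, 10⁶
toxicity threshold, 100 initial cells, 10,000 iterations and 3 replicates
are the modelled experiment; the transcription/decay probabilities, the
logistic initiation form and softness, the death/division probabilities,
the division attempt rate, the jitter law, the tracked-sample cap and the
baseline death rate are this package's choices, all surfaced in
`SimConfig`. The constants must satisfy one consistency constraint worth
spelling out: a producing cell gains roughly 290 proteins per iteration
(45 plasmids × 0.5 transcription × ~13 lifetime translations per mRNA), so
it crosses the 10⁶ toxicity threshold after ~3,500 iterations — the
baseline death rate must leave cells alive that long (5 × 10⁻⁵ gives a
~20,000-iteration horizon) or toxicity never engages and the protein-cost
phenotype cannot emerge. Within these dynamics the two qualitative
signatures of interest are emergent, not scripted: endpoint protein per
cell falls with opening energy, with a plateau (diminishing returns) below
the optimum where toxicity caps per-cell accumulation, and constructs that
produce more protein end with fewer cells (protein cost). The summary
reports Spearman correlations at both aggregation levels — over all
construct × replicate points and over replicate averages — since both
readings of "correlation across replicates" are defensible.

Two numerical choices: binomial draws with more than 10,000 trials per
entry use the clipped rounded normal approximation (relative error in the
draw's sd < 0.3% there, far below the process noise); and per-construct ×
replicate simulations use independent child streams of one seed sequence,
so results are bit-reproducible per seed and replicates are independent.

## Problem sizes in the test suite

Test and script problem sizes are the package's own desk-scale choices:
toy-engine oracle agreement on 100 random sequences ≤ 22 nt; annealing
optimality on 20 instances with 4 substitutable codons; the nine-vs-full
comparison on 12 random 16-codon constructs with reduced chain counts; AUC
pair-counting on 50 datasets of n ≤ 50; 4PL recovery over 100 noise seeds;
score recovery over 50 fixtures of n = 5,000; and the simulator at its full
default configuration over 3 seed sets. The production folding engine is
exercised directly in the suite (it is a hard dependency only of the
production code path, not of the library import).

## Known limitations

* The toy energy model is non-physical by design; only the production
  engine produces kcal/mol values comparable to published opening energies.
* Expression Scores from a model fitted on synthetic fixtures are not
  transferable to real constructs; refitting on a real labeled campaign
  (tabular id/opening_energy/outcome input to `fitscore`) is required.
* The simulator is a minimal birth–death/burden model: no Gillespie exact
  kinetics, no plasmid loss, no nutrient limitation, no mRNA baseline decay,
  and its unstated constants are defaults, not fitted quantities.
* Terminator scanning is exposed only as a disabled external-command hook;
  pseudoknots, RNA–RNA interaction structure prediction and solubility
  modelling are out of scope.
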