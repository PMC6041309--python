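# Methods

## The decontamination model

The filter assumes that reagent/instrument contamination contributes a
*shared* community to every sample processed in a batch, and that empty
sampling-device controls sequence that community alone. Each feature
(denoised 16S sequence, "genotype") is judged per sample by comparing
relative abundances:

* absent from every control → `sample_only`, accepted;
* present in controls, sample abundance strictly greater than
  `ratio_threshold` × control abundance → `accepted_shared`;
* otherwise → `rejected`.

The inequality is strict ("more than *t* times"), so a ratio exactly at
the threshold rejects. The default threshold is 4. Control samples are
never filtered; they are carried through for reporting. After
decontamination, features with fewer than 250 reads summed over the
non-control samples are removed (strict <; a feature at exactly 250
survives). The rarity total excludes control reads because controls are
not part of the analyzed dataset.

Decisions that were genuinely open, and how they were made:

* **Per-sample verdicts.** The ratio test uses each sample's own
  relative abundances, so a shared genotype can be accepted in a
  high-load sample and rejected in a low-load one. A dataset-wide
  verdict could not produce per-sample read-fraction breakdowns and
  would let a single dominant sample decide for all.
* **Control pooling.** By default counts are summed over all controls
  into one profile before normalizing (`pooled`). Controls retain very
  few reads, so per-control relative abundances are noisy;
  pooling stabilizes the denominator. A `max_per_control` mode (the most
  conservative per-control summary) is available.
* **Known caveat.** This filter trades sensitivity for specificity:
  because control read totals are small, a handful of control reads can
  give a feature a high control relative abundance and reject genuinely
  present taxa. The synthetic evaluation quantifies exactly this via
  `evaluate_recovery`.

## qPCR quantification

Loads are 16S copies per swab. When only Ct values are available,
copies = dilution · 10^((Ct − intercept)/slope) with a user-supplied
standard curve (slope < 0 in Ct per decade); estimates outside the
curve's dynamic range are flagged but returned, since the remedy
(diluting further before amplification) is upstream of analysis. The
shipped default curve has perfect-efficiency slope −log₂10 ≈ −3.32.
Group comparisons use medians (midpoint convention for even n, hence
ratio(a,b)·ratio(b,a) = 1) and the two-tailed Mann–Whitney U test:
exact enumeration when the combined sample size is ≤ 16 with no ties
(feasible to enumerate, and copy numbers rarely tie), otherwise the
normal approximation with tie and continuity corrections.

## Diversity and core taxa

Shannon diversity uses the natural logarithm (the base is a convention;
it is stated here because values are not comparable across bases). Hill
numbers are (Σ pᵢ^q)^(1/(1−q)) with the exact limits at q = 0
(richness) and q = 1 (exp Shannon). No rarefaction is applied before
diversity computation; unequal depths therefore inflate richness-type
orders in deeper samples, a documented caveat.

Core taxa of a group are genus-level taxa with median relative abundance
strictly above `abund_min` (default 0.1 %) in at least `prev_min`
(default 75 %, inclusive) of the group's samples. Medians and SDs are
taken across **all** of the group's samples, absences contributing
zeros — required for taxa that are core by prevalence yet have low
median abundance. "Detected" means ≥ 1 read; where an analysis needs a
stronger detection rule it states one explicitly (the co-existence
matrix uses ≥ 20 reads). Prevalence percentages are rounded to whole
percent. Genus-level aggregation keys on the full lineage prefix, so
placeholder taxa under different families (e.g. unclassified
Lachnospiraceae vs unclassified Ruminococcaceae) remain distinct taxa,
and they count as taxa in all taxon tallies.

## Similarity analyses

Spearman correlations between two samples are computed over the full
genus list of the table (union of genera, zeros filled). This is the
only convention that makes ρ comparable across pairs; the many tied
zeros are handled by average ranks. Pairs in which either vector is
constant are undefined and returned as flagged missing values.

The Friedman statistic uses within-block average ranks with the
standard tie-corrected chi-squared form, df = k − 1. The chi-squared
reference is an approximation: at very small block counts (n ≈ 4) its
tail agrees with the exact permutation null to ~0.02 only for large
statistics, while mid-range p-values can deviate by up to ~0.18 — a
property of the approximation itself, shared by the standard R and SPSS
implementations. The Nemenyi post hoc standardizes each mean-rank
difference by √(k(k+1)/(12n)) and refers it to the studentized-range
distribution with k groups and infinite df, matching the
unreplicated-blocked-data q approximation of the R package PMCMR.

Bray–Curtis dissimilarity is 1 − 2Σmin(x,y)/(Σx+Σy); the triangle
inequality is not guaranteed and not asserted. PCoA is classical
scaling: double-center −½D², eigendecompose, scale eigenvectors by
√eigenvalue. Negative eigenvalues (non-Euclidean inputs such as
Bray–Curtis) are excluded from the coordinates and from the
variance-explained denominator, which is the sum of positive
eigenvalues — one of several conventions in circulation, chosen to
match the most common classical-scaling implementations; affected
results carry a flag.

Venn partitions of shared taxa define presence in a group as median
relative abundance > 0, i.e. detection in a strict majority of the
group's samples. The co-existence matrix restricts to taxa with
≥ 20 reads in more than half of the calves, and reports for each dam
site the fraction of dams reaching ≥ 20 reads among dams whose own calf
carries the taxon.

## The synthetic generator

Each sample mixes a true community and a single batch-wide contaminant
community in proportion to 16S copy numbers (w = T/(T+C)), then draws
reads multinomially at the group's sequencing depth. Defaults encode
the emulated study design: 21 calves × 3 time points, 10 dams × 3 body
sites, 3 empty-swab controls; contamination 1.3·10⁵ copies per swab;
newborn load 5.7·10⁵ copies, rising 7000× by 24 h and a further 14× by
7 d; per-group depths are the study's per-group raw-read medians
(4 486–76 993). Dam loads (10⁸–10¹⁰) are typical of high-biomass adult
sites. qPCR "measurements" are T + C with multiplicative log-normal
noise (σ = 0.1), and per-swab loads and depths carry log-normal jitter
(σ = 0.2 and 0.3).

Community structure: each dam site has a log-normal base profile
(σ = 1.5) over a random ~60 % subset of the 120-genotype true pool,
perturbed per dam by a Dirichlet with concentration 50 (moderate
between-dam variation). Newborn calves draw their community from their
own dam's sites with weights 0.7 oral / 0.2 vestibule / 0.1 feces —
planted oral-dominant vertical transmission. 24 h communities collapse
onto a facultative-anaerobe profile dominated (~77 %) by an
*Escherichia/Shigella* genotype; 7 d communities shift to an
anaerobe-rich profile (*Faecalibacterium*, *Bacteroides*,
*Lactobacillus*, *Butyricicoccus*, *Bifidobacterium*) with a log-normal
tail; both carry 5 % of the preceding time point. The contaminant pool
(40 genotypes, log-normal σ = 1 — reagent communities are modeled as
moderately even, which also keeps every contaminant detectable in
pooled controls) is biased toward genera commonly reported from
reagents, and overlaps the true pool by a configurable fraction
(default 10 %), the dominant facultative genotype among them. Origin
labels, not names, are authoritative.

Randomness uses numpy's default PCG64 generator seeded once per study;
identical seeds give bit-identical datasets across platforms.

What the generator does **not** model — hence what passing tests do not
show about real data: PCR/chimera artifacts, base-level sequencing
error, taxonomic misclassification, preamplification-cycle bias (cycle
counts are recorded in metadata but have no effect), well-to-well
cross-contamination, and dispersion of the contaminant profile across
control replicates (a single shared profile with multinomial noise is
used). In particular, the clean separation that yields 100 %
true-read retention holds because true-only genotypes genuinely never
enter controls; in real data closely related sample and control
sequences can collide at the resolution limit of 16S.

## Numerical choices and degenerate inputs

Counts are integers throughout; relative abundances are a derived view.
All-zero samples are flagged, not errors, and yield all-zero relative
abundances and NaN diversity. Empty controls make decontamination
undefined and raise. SDs reported next to medians are sample SDs
(ddof = 1), 0 for n = 1. PCoA eigenvalue positivity uses a relative
1e-12 tolerance. Studentized-range tail probabilities are evaluated at
infinite df. Incomplete dam–calf blocks are dropped whole (with a log
message) rather than imputed.
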