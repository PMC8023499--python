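# Methods

## Scope and data model

All coordinates are 0-based, half-open (BED semantics); an origin's
"midpoint" is the integer floor of its interval center. Origin tables are
pandas DataFrames anchored on oriented ACS positions; fragment sets are
DataFrames of `(chrom, start, end, length, sample)` with a 650 bp length
ceiling mirroring the paired-end mapping cutoff used for MNase ChIP
libraries. Coverage tracks are fixed-width binned arrays carrying a
normalization state; the only legal state paths are
`raw → cpm → background → input_subtracted` (depletion workflow) and
`raw → spikein → input_subtracted` (spike-in workflow). Any other order
raises an error rather than silently producing incomparable tracks.

## ChIP quantification

Coverage bins hold mean per-base fragment depth (computed exactly via a
difference array and cumulative sum), matching bedGraph semantics; V plots
and density profiles instead count fragment midpoints, which preserves the
point geometry of fragment-size analyses. "Non-origin background" is
defined as bins whose center lies more than 2.5 kb from every confirmed
origin midpoint — beyond the 1 kb quantification window plus the ±3
nucleosome reach of origin-proximal MCM — and the summary statistic is the
median, making background normalization insensitive to outlier bins and to
any positive rescaling of the input track. Per-origin signal is the *sum*
of bin values whose centers fall in the 1 kb window centred on the
midpoint (correlation statistics are invariant to sum-vs-mean; the choice
is recorded here). Windows overhanging a chromosome end are flagged
invalid instead of clipped. Post-subtraction negative values are retained;
downstream statistics apply the positive-control-signal filter
explicitly. Quartiles of percent-signal-lost use the ≤25/50/75 percentile
rule with ties to the lower quartile. The top-fraction origin set sorts by
descending signal (ties by name) and takes the shortest prefix reaching
the target share of total signal; because any set of k signals is
dominated by the k largest, the greedy prefix is minimal, and this is
asserted on every call. V-plot offsets are negated for minus-strand ACSs
so "downstream" always means downstream of the ORC-binding motif;
upstream/downstream directional splits use the same reflection, with exact
ties broken to upstream and flagged.

## T_rep estimation

T_rep is the time at which half the cells have replicated a bin. The
estimator: (1) counts-per-million per sample, per-bin ratio to the
earliest sample, which is assumed unreplicated; (2) bulk-content
restoration — within-sample depth normalization makes a uniform doubling
invisible, so the copy scale must be re-anchored per timepoint. Early in
the course, while some loci have not begun replicating, the low quantile
(default 5th) of the locally smoothed ratio field (default 9-bin moving
average; forks make true T_rep spatially smooth, so local averaging is
principled) equals the reciprocal of the content factor; these lower
bounds are forward-accumulated since content is non-decreasing. Once
enough bins (≥ max(20, 2%)) were confidently fully replicated at the
*previous* timepoint, those bins anchor the factor directly at copy ratio
2 — replication is persistent, so the anchor set only grows. A final
affine map with fixed point at ratio 1 pins the genome-wide median of the
last timepoint to 2.0, and is skipped when the final sample shows no
detectable replication (median ratio within 0.2 of 1), which keeps
degenerate no-replication inputs at ratio 1. (3) Replicated fraction
`f = clip(ratio − 1, 0, 1)` with per-bin isotonic regression over time
(scipy's pool-adjacent-violators); (4) linear interpolation of the 0.5
crossing between bracketing timepoints. Bins that never reach 0.5, or
start at/above it, are masked and counted in the profile diagnostics.
At least 7 timepoints are required.

Smoothing uses statsmodels LOWESS (degree-1 local fits, tricube weights)
with span = window / chromosome extent, default window ≈ 50 kb; linear
profiles are reproduced exactly by construction. Subtelomeric masking
removes bins overlapping the outer 15 kb of each chromosome (timing
estimates there are dominated by noise in real data). Overlay alignment
between conditions subtracts the difference of the 5th percentiles of
valid smoothed T_rep — the earliest-replicating regions — because a
global initiation delay shifts the whole distribution while the earliest
regions are least confounded by condition-specific late-replication
changes; the percentile is configurable.

Known estimator limitation: absolute T_rep from real depth-normalized
data is identifiable only through the content anchors above; if the
reference sample already contains replicated cells, all T_rep values
shift by a common monotone transform. Overlay alignment absorbs a uniform
shift, and all rank-based and delta statistics are unaffected.

## Loading and firing models

Licensing competition is a Markov jump process on origins i with ORC
activity `a_i` (per free MCM-DH per minute) and capacity `c_i` (MCM-DH
units): propensity `a_i · n_free · 1[m_i < c_i]`, simulated exactly
(Gillespie) until G1 ends or the pool is exhausted. `Σ m_i + n_free = N`
holds at every event. Mass action in the free pool (rather than
constant-rate loading) makes pool size, not elapsed time, the binding
constraint when MCM is depleted — with the endogenous pool in excess,
neither time nor abundance limits loading and every origin reaches
capacity. Model variants: `orc_activity` (capacities infinite; an
exhausted pool splits multinomially with probabilities `a / Σa`, so
reduction is proportional for every origin), `capacity` (equal
activities), and `hybrid` (both vary). The mean-field companion
integrates `dm_i/dt = a_i n_free` exactly between capacity-freeze events
(the free pool decays exponentially with rate `A = Σ active a_i`); it is
the exact stochastic mean when no origin saturates and a deterministic
approximation otherwise.

Firing: each loaded MCM-DH is an independent potential initiation event
with rate λ, so an origin with occupancy m fires at `Exp(m·λ)` — higher
stoichiometry means earlier average firing; `m = 0` never fires. Forks
move at constant speed v; a position replicates at the earliest
`t_fire + distance/v` over origins on its chromosome (passive replication
included), and simulated T_rep is the per-bin time by which ≥ 50% of
cells have replicated. Limiting initiation factors, replisome-level
mechanism and rereplication control are deliberately out of scope; the
independent-exponential firing law is the minimal stochastic model
linking occupancy to timing and is a documented extension point.

Defaults: λ = 0.05/min and v = 1.5 kb/min (of the order of measured
yeast fork speeds), G1 = 90 min, 100 cells per profile. None of these is
an estimate from data; they set a desk-scale regime in which firing-time
differences between well- and poorly-licensed origins are resolvable
within one S phase.

## Synthetic data: what it emulates, and what it does not

`sample_chip_fragments` reproduces the fragment-size anatomy of
MNase-digested MCM ChIP around oriented ACSs: MCM-DH-sized fragments
(50–90 bp, mode 68) centred in the nucleosome-free region (|offset| ≤ 80
bp) and nucleosome-sized fragments (125–165 bp, mode 146) at ±{165, 330,
495} bp with decreasing weights (0.5/0.3/0.2) and ±15 bp positional
jitter, reflected for minus-strand origins. The subnucleosomal share is
`p_nfr × digestion_level` (default p_nfr = 0.3): lightly digested
chromatin yields few subnucleosomal fragments. Per-origin fragment counts
are multinomial in ground-truth occupancy; a configurable fraction of
fragments is uniform genomic background. The mixture proportions are
plausible placeholders, not estimates — no published quantitative NFR/
nucleosome mixture exists to match. Input samples are a uniform
nucleosome ladder (85% mononucleosome around 146 bp, 15% dinucleosome);
real input tracks additionally carry origin-adjacent nucleosome
structure, MNase sequence bias and mappability structure, none of which
is modelled. Sequence-level ACS motifs and nucleosome-positioning
thermodynamics are out of scope. Sync-seq counts are Poisson around
`depth × (1 + f_b(t))` with a probit per-cell dispersion
`f_b(t) = Φ((t − T_b)/σ_cell)`, σ_cell = 4 min by default — the minimal
counting-noise model; overdispersed (negative binomial) noise is not
simulated, so passing tests bound estimator error under ideal counting
noise only.

## Genome-scale study conditions

`mcmkit.experiment` assembles the desk-scale reproduction of an MCM
depletion / overexpression study on a sacCer3-sized genome (the 16
standard chromosome lengths, ~12.07 Mb) carrying 410 confirmed origins
apportioned by chromosome length with ≥ 2 kb spacing. Ground truth per
origin: capacity drawn from a gamma distribution (shape 2.5, mean 10
MCM-DH, clipped to [1, 40]) giving the right-skewed per-origin signal
distribution characteristic of licensing ChIP; ORC activity proportional
to capacity^1.7 with lognormal scatter (σ = 0.4), so poorly licensed
origins also load fractionally slower — the hybrid-model coupling (with
activity exactly proportional to capacity, per-capacity fill rates would
be identical across origins and origin classes would not separate under
depletion). Class labels follow activity terciles (30% weak / 40%
chromatin-dependent / 30% DNA-dependent). The endogenous pool is 20× the
summed capacity (MCM far in excess of what is loaded), and the depletion
series reduces it to 14% and 7% of endogenous levels — the degree of depletion an
auxin-degron knockdown of Mcm4 achieves at intermediate and strong doses. The absolute kinetic scale (0.05 per
capacity unit at full pool) and the pool excess were fixed by fitting the
simulator's class-level signal retentions to the class-level retentions
such depletion experiments report (DNA-dependent 109–94%,
chromatin-dependent 100–77%, weak 74–48% across the two doses) — and to nothing else; the top-50%
origin counts and inter-origin distances are then measured outcomes.
The fit is imperfect and the residual is a known limitation: the
simulated dose-response is steeper than the reported one (the weak class
retains too much at the intermediate dose and too little at the strong
dose), so summary statistics at the intermediate dose change less than
reported while the strong dose is closer. ChIP libraries are sequenced to
fixed depth with a constant nonspecific background yield, so depleted
conditions contain proportionally more background — which the background
normalization step is designed to absorb.

The overexpression comparison saturates loading in both conditions
(relative per-origin occupancy is unchanged when MCM is already in
excess) and models the treated library as recovering 59% as many
target-genome fragments per spike-in read — the uniform absolute reduction such
galactose-overexpression ChIP comparisons report, treated here as a
property of the ChIP rather than of loading. The pipeline then has to *recover* that
uniformity (near-perfect between-condition correlation) and the ~41%
mean decrease through spike-in normalization and input subtraction with
realistic counting noise.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere; identical seeds give byte-identical
fixture files. Sub-seeds for pipeline stages are drawn from a parent
`numpy` Generator and kept below 2^31. Zero-fragment inputs produce
empty, valid outputs; an all-zero background or a zero spike-in count is
an error, as is CPM normalization with no source fragments. If every ORC
activity is zero the loader returns zero occupancies with a warning
record rather than an error. Fragment placement near chromosome ends is
shifted inside rather than clipped, preserving lengths. Mean-field
capacity freezes snap exactly to capacity to avoid round-off drift.
The even-n "time by which ≥ 50% of cells replicated" uses the
⌈n/2⌉-th order statistic rather than the averaged median, so a
single-cell profile equals its closed form exactly.
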