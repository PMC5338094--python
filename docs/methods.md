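# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated on, the defaults and why, and the numerical choices
made where the design was open.

## Droplet digital PCR quantification

**Model.** Each droplet receives a Poisson-distributed number of template
molecules with per-channel mean λ; a droplet is positive iff it received at
least one, so the positive fraction is `p = 1 − e^{−λ}` and the estimator is
the inversion `λ̂ = −ln(1 − p̂)`. Copy number per diploid genome is the
concentration ratio scaled by the reference's diploid copy count,
`CN = c_ref · λ̂_target / λ̂_ref` with `c_ref = 2` by default (autosomal
single-copy reference). Droplet volume cancels in the ratio; an absolute
copies/µL output using the nominal 0.85 nL droplet volume is provided but
not needed for copy number.

**Intervals.** A 95% Wilson interval on `p̂` is transformed through
`−ln(1−·)` per channel; the CN interval is the ratio of bounds
(`target_low/ref_high`, `target_high/ref_low`). Wilson is used because it
behaves sensibly at `p̂` near 0. Saturation (`p̂ = 1`) is an error, not a
clamp: a fully positive plate carries no concentration information.

**Summaries.** Histograms use half-open bins centered on multiples of the
bin width (default 0.5 copies, configurable — the binning granularity of a
population CNV figure is a presentation choice). Population summaries report
the sample (n−1) standard deviation and mark SD undefined for n = 1.

**Simulator.** `simulate_droplets` draws
`positives ~ Binomial(n_droplets, 1 − e^{−λ})` per channel with
`λ_target = λ_ref · CN_true / c_ref`. Defaults: `λ_ref = 0.2` (a typical
~1 ng loading), 20 000 droplets (a realistic per-well count for a
QX100-class instrument). Estimator-recovery checks use 10⁶ droplets per
channel so that sampling noise is far below the 1% bias tolerance being
tested. The simulator models no rain (ambiguous droplets), no volume
variation and no channel crosstalk, so passing tests demonstrate the
correctness of the Poisson inversion, not robustness to gating artifacts.

## Read-depth copy-number estimation

**Model.** With a collapsed multi-copy locus, reads from all copies map to
the representative reference locus, so region depth is proportional to the
total haploid multiplicity m. The estimator is
`CN = 2 · Σ_r mean_depth(r) / background_depth`, summed over all
paralog-homologous reference loci: one reference locus at background depth
scores exactly 2. The diploid scaling constant is explicit and overridable
(haploid or ancient samples).

**Background.** "Overall depth" defaults to the mean over user-supplied
background regions (or the complement of the paralog regions); a median
option exists for contamination-robust use. Mean is the default because the
simulator's Poisson depth is symmetric and the estimator is a ratio of
means. No GC-bias or mappability correction is applied — a deliberate
fidelity-over-sophistication choice, flagged as a limitation for real data
where both effects bias depth ratios.

**Simulator.** Depth at base i is `Poisson(coverage · m_i / 2)` with
background multiplicity 2. Recovery checks use a 10 kb locus at coverage 30
(error tolerance 0.3 copies); at these sizes the standard error of the
region mean is ≪ the tolerance. The simulator has no read-length
autocorrelation, no mapping ambiguity beyond the collapsed-multiplicity
idealization, and no reference bias; the multi-mapper behavior of a real
aligner over near-identical paralogs is idealized as full collapse.

## Distance phylogenetics and the concerted-evolution statistic

**K2P distances.** Over sites where neither sequence of a pair has a gap or
ambiguity code (pairwise deletion — the ambiguity exclusion is our
tightening of the usual gap rule, chosen to fail safe on IUPAC codes):
transition proportion P, transversion proportion Q,
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`. Arguments ≤ 0 raise a saturation
error rather than returning infinity. Protein alignments fall back to
p-distance, since K2P is a nucleotide model.

**Neighbor-joining.** Standard Q-criterion agglomeration. Determinism
choices: the Q matrix is computed as `(n−2)D − (r_i + r_j)` with the row
sums added before subtraction so it is exactly symmetric in floating point;
ties are broken by the lexicographically smallest pair of cluster
representative labels (a cluster is represented by its smallest leaf
label). Negative branch estimates are clamped to zero with the deficit
transferred to the sibling branch, preserving path lengths through the
join. On additive matrices NJ is exact; tests verify topology and path
lengths to 1e−9 against randomly generated additive trees, with exhaustive
topology enumeration as an independent oracle up to 6 leaves.

**Bootstrap.** Columns are resampled with replacement; each replicate is
rebuilt with NJ; supports are the percentage of completed replicates
containing each split of the full-data tree. Only splits on internal
branches of positive length count as resolved (an alignment of identical
sequences yields no supports). Replicates with a saturated pair are skipped
and counted, with a warning; supports are percentages of completed
replicates. 500 replicates is the conventional default.

**W/B statistic.** W is the mean pairwise distance among copies of the same
species, B the mean across species (all pairs, not only orthologous ones).
Under divergent evolution with the duplication predating the species split,
W/B > 1 (within-species pairs include old paralog splits); interlocus gene
conversion drives W/B below 1 and makes each species' copies monophyletic
on the NJ tree — both are reported. The monophyly flag is read off the NJ
bipartitions.

**Family simulator.** A star duplication into k paralogs at depth 0.15
(expected substitutions per site at rate 1), speciation of every paralog
lineage at depth 0.05, sequence evolution under the K80 process
(transition/transversion rate ratio κ = 2, the classic genome-wide
average). These depths put within-species paralog divergence (~0.3) and
orthologous divergence (~0.1) in the range seen in young primate gene
families while keeping distances far from saturation. Defaults: 4 paralogs
per species, 2000 sites. Gene conversion is applied after substitutions
have accrued, as Poisson(rate)-many unidirectional tract copies per tip
lineage from a uniformly chosen within-species donor, tract length 30% of
the alignment placed uniformly — the simplest mechanism that produces the
homogenization the statistic is designed to detect. Conversion at the tip
(rather than interleaved in time) is a maximally homogenizing
idealization; detection rates on this generator are therefore an upper
bound on power against temporally dispersed conversion.

## CRISPR amplicon indel calling

**Alignment.** Global Needleman–Wunsch with affine gaps (Gotoh three-state
DP; match +1, mismatch −1, gap open −4, gap extend −1, a gap of length L
costing `−4 − L`). Traceback ties resolve match > deletion > insertion for
cross-platform determinism. Scores are verified against an exhaustive
alignment enumerator on small sequences. Alignments are cached per distinct
read haplotype, since amplicon libraries are highly redundant.

**Calling.** The net indel length (inserted − deleted bases) within
cut_site ± window (default 20 bp) determines the class: 0 → unedited
(cancelling indels leave the frame intact), multiple of 3 → in-frame,
otherwise frameshift. Judging the net length rather than individual events
mirrors the reading-frame consequence, which is what matters functionally.
A clone is "high" when its frameshift fraction reaches the configured
threshold (default 0.5 — a required, logged choice; no canonical value
exists).

**Spacer scanning.** Every position on both strands where a spacer-length
window is immediately followed by the PAM (default NGG; IUPAC codes
supported). Default spacer length 19 nt, matching a 5′-trimmed SpCas9
guide; 20 nt available by flag.

**Simulator.** Each read is the reference (probability
`unedited_fraction`) or carries exactly one indel drawn from the stated
spectrum at the cut site (deletions centered on it); one indel per read, no
sequencing errors by default (an optional substitution-error rate exists).
This isolates the counting logic: exact-recovery tests compare called class
counts to the simulator's ground truth read by read.

## Sequence utilities

Protein molecular weight is the sum of average (not monoisotopic) residue
masses plus one water (18.0153 Da), using Biopython's average-mass table;
predicted-weight conventions for gels use average masses. Only the 20
standard uppercase residues are accepted — lowercase and U fail loudly
rather than contributing a silently wrong mass. kD values are reported as
Da/1000 rounded to the nearest integer.

## Problem sizes and determinism

All generators are bit-reproducible given (config, seed); every stochastic
test and the acceptance script derive their seeds from a single base seed.
The validation sizes — 10⁶ droplets × 11 copy-number states × 20 seeds,
four multiplicities × 20 depth simulations, 200 random additive matrices,
50 family simulations per conversion regime, 500 bootstrap replicates on 20
taxa — were chosen so each stage's sampling error is comfortably below the
tolerance being asserted while the full suite runs in well under a minute
of compute per stage.

## Known limitations

* No droplet gating from raw fluorescence; quantification starts from
  positive/negative counts.
* The depth model ignores GC bias, mappability and real multi-mapper
  behavior; estimates on real genomes need those caveats.
* No alignment construction: multiple alignments are consumed, not built.
* The W/B statistic aggregates; it does not locate conversion tracts.
* No off-target scoring for spacer sites and no per-paralog read
  demultiplexing of amplicon reads.
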