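# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data (`ancientkin.simulate`)

The generator is the package's source of ground truth. It emulates the
statistical structure of shotgun sequencing from poorly preserved Neolithic
skeletal samples, at desk scale.

**Genome layout.** One synthetic contig per compartment — autosome
(default 100 kb), X (20 kb), Y (2 kb), mtDNA (16 kb) — with uniform random
base composition. This avoids any real-genome download while preserving the
quantities the estimators consume (compartment lengths, X:Y length ratio,
site positions). The default X:Y ratio of 10:1 puts the expected male Ry at
y/(x+y) ≈ 0.091, in the empirical range of genuine XY shotgun data
(≈ 0.08–0.09) and safely separated from the 0.075 decision threshold.

**SNP panel.** Balding–Nichols: per site an ancestral frequency
p ~ U(0.05, 0.95); population k drifts to
f_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so Var(f_k) = F_k·p(1−p) — the
moment checked by the generator tests. Sites are restricted to transversion
ref/alt pairs (the ref allele is the genome base) because the downstream
genotyping model is transversion-only by design. Panel individuals are
binomial diploid draws; admixed individuals draw from mixture frequencies
Q·F. Default drift F = 0.1 per population: continental-scale
differentiation, appropriate for source populations as distinct as European
Neolithic farmers and steppe pastoralists; the MDS recovery study uses
F = 0.05 deliberately, as a harder, more finely structured case.

**Reads.** Fragment lengths are lognormal (σ_log = 0.35) around a
configurable mean, default 45 bp; empirical ancient fragment-length
distributions are right-skewed with means around 39–45 bp, and the family
is configurable because the true distribution is library-dependent. Reads
are placed uniformly per compartment at ploidy-scaled coverage, with the
mtDNA boosted by a copy-number factor (default 50, matching the observed
ratio of mitochondrial to nuclear depth in real screening data).
Deamination is applied to endogenous reads only: 5′ C→T at rate
δ·decay^(p−1) with geometric positional decay (default decay 0.5), and the
mirror-image 3′ G→A, which is the signature of double-stranded blunt-end
libraries. Sequencing errors are uniform base substitutions (default
10⁻³). Contaminant reads (a configurable fraction) come from an undamaged
present-day XX individual: a fixed mtDNA haplotype diverged from the
endogenous lineage by one transversion per 100 bp (making contamination
identifiable at desk scale), nuclear alleles drawn from population-0
frequencies, and no Y reads. Endogenous content is encoded as the ratio of
emitted mapped reads to a recorded raw-read total, since the unmapped
(microbial) fraction itself carries no information the pipeline uses.

**Haplogroup trees.** Balanced synthetic trees (default depth 2, two
children per node, four defining variants per branch) whose defining
variants are transversions at unique positions — so deamination can never
mimic a defining allele, which is also why damage masking provably cannot
move placements on these trees.

**Reproducibility.** One root seed; every consumer derives an independent
stream keyed by stable CRC32 hashes of component and sample names, so
outputs are byte-identical across runs and independent of sample order.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: reference bias and mapping error (reads are
placed, not aligned), indels and structural variation, UDG-treated library
chemistry, linkage disequilibrium between panel sites (sites are
independent), heterogeneous per-base quality profiles, and realistic
population history (drift is a one-parameter star phylogeny, not an
admixture graph). Estimator behaviour under those conditions must be
established on real data.

## Read QC and damage (`ancientkin.qc`)

Filtering keeps reads with MAPQ ≥ 30 and length ≥ 30 bp, both inclusive.
The screening rule passes a sample when endogenous ≥ 0.5% **and**
first-position 5′ C→T ≥ 10%; these boundaries are the inclusive complement
of the exclusion rule stated as "below 0.5%" / "below 10%". Duplicate
collapse keys on (contig, 5′ alignment position, strand, length) — the
start-position semantics appropriate for single-end data — keeping the
highest summed base quality, ties broken by lexicographically smallest
sequence. Damage profiles re-orient reverse-strand reads to fragment
orientation before counting; positions with zero opportunities are reported
missing, never zero. The damage window default is 25 positions (no
standard value exists; 25 comfortably contains the geometric decay).
Damage statistics are computed after duplicate collapse, since duplicates
would otherwise double-count damaged molecules. The SAM reader accepts only
pure-match CIGARs; soft-clipping is out of scope and such records are
tallied and skipped.

## Sex and contamination (`ancientkin.sexcontam`)

Ry thresholds 0.075 (XY) and 0.016 (XX) are the published decision criteria
for shotgun sex assignment; the CI is the binomial normal approximation
ry ± 1.96·√(ry(1−ry)/n).

mtDNA consensus: majority rule over reads with 7 bp trimmed from each end
(deamination is concentrated there), minimum depth 3, ties and thin sites
emit N.

mtDNA contamination is a two-component per-read mixture: per-base terms
(1−ε) for match and ε/3 for mismatch against either the sample consensus or
each candidate contaminant haplotype, mixture weight c on the contaminant
side, ĉ maximized on a 0.001 grid over [0, 1]. All terminal bases (7 bp)
are excluded from the likelihood, not just transition mismatches — a
stronger guard against damage confounding that also matches the consensus
convention. When ε is not supplied it is estimated from the mismatch rate
at positions where consensus and all panel haplotypes agree (floor 10⁻⁴).
The 95% CI is the profile-likelihood set within 1.92 log units (χ²₁) of
the maximum — a deliberate, documented difference from the Bayesian
posterior intervals of the tool this estimator stands in for.

X contamination (males only, X depth > 0.5×) is a transparent method of
moments rather than a full likelihood: ĉ = (m_poly − m_mono)/mean[2f(1−f)],
clamped to [0, 1], CI from 200 site-bootstrap resamples. Two robustness
details matter in practice: polymorphic sites enter only at depth ≥ 2,
because a site covered by a single read can never exhibit a minor allele
and would only dilute the numerator; and C→T / G→A mismatch types are
excluded from the monomorphic error control, because terminal deamination
otherwise dominates it (the polymorphic sites themselves are
transversion-typed, so damage products never count as alleles there).

## Haplogroups (`ancientkin.haplo`)

SNP status per defining variant (ancestral/derived/missing/conflict) uses
BQ ≥ 30 bases; with damage masking on (the default for Y calls from raw
reads), C↔T and G↔A defined variants are ignored entirely, consistent with
unrepaired library chemistry. Masking defaults off for consensus-based
mtDNA calls because majority consensus already suppresses sporadic damage.

mtDNA assignment ranks haplogroups by the Kulczynski-style score
½(|E∩O|/|E∩covered| + |E∩O|/|O|); ties break on shallower depth, then
name. The full rank heuristics of dedicated mtDNA classifiers (hotspot
weighting, private-mutation penalties) are intentionally out of scope, so
the score is comparable across samples but not numerically comparable to
those tools' quality percentages.

Tree placement is parsimony — maximize (derived support − conflicts) over
root-to-node paths — replacing likelihood-based phylogenetic placement,
which would require a reference alignment and substitution-model fitting
that desk-scale synthetic data cannot meaningfully constrain. The
input/output contract (statuses in, best node with support/conflict/margin
out, internal placements allowed) is the same. Ties prefer the shallower
node, which is what produces honest basal calls when support is confined to
a shared internal branch.

## Population genomics (`ancientkin.popgen`)

Pseudohaploid calls sample uniformly among passing (MAPQ ≥ 30, BQ ≥ 30)
ref/alt bases; third alleles are excluded before sampling. Panel diploids
are haploidized (random allele per site, seeded) before IBS with ancients
so distances are computed on uniform ploidy — mixing diploid and haploid
comparisons would bias p(IBS). Pairs overlapping fewer than 500 sites
(configurable) are flagged and excluded from MDS; no published floor
exists, 500 keeps the binomial noise on a pairwise distance below ~0.011.

Classical MDS is Torgerson double centering, B = −½·J·D²·J, with
eigen-decomposition, coordinates scaled by √λ and a deterministic sign
convention (first nonzero loading of each axis positive).

The admixture model is the standard binomial likelihood with per-individual
allele counts c_i (2 diploid, 1 pseudohaploid); missing entries contribute
nothing (missing-at-random). Updates are EM (block relaxation) rather than
quasi-Newton acceleration: simpler, and provably monotone in log-likelihood
— asserted every iteration in the tests. F is clipped to
[10⁻⁶, 1−10⁻⁶] to keep the likelihood finite; convergence is relative
log-likelihood change < 10⁻⁶ (default), max 2000 iterations with a warning
on non-convergence. Q is initialized per individual from a stream keyed on
the individual's genotype row, so identical individuals provably follow
identical trajectories (and duplicate-row tests can assert exact equality).
Replicate alignment solves the column-matching problem with the Hungarian
algorithm on squared-error cost (optimal where a greedy column match is
only heuristic); modes are connected components under pairwise aligned-Q
RMSE < 0.05, the major mode is the largest (ties to higher mean
log-likelihood), represented by its highest-likelihood member.

## Chronology and diet (`ancientkin.chrono`)

Calibration evaluates posterior(θ) ∝ exp(−(m−μ(θ))²/(2(σ²+σ_curve(θ)²)))
on a 1-yr grid with linear curve interpolation, normalizes on the grid, and
reports 95.4% highest-posterior-density intervals — the multi-interval
convention of standard calibration software, not central quantiles. The
HPD cell set is tie-inclusive (cells with density equal to the threshold
cell all enter), so symmetric posteriors give symmetric intervals; interval
endpoints are rounded outward to whole years; total HPD mass is asserted to
lie in [0.954, 0.97]. Calendar conversion uses the 1950 CE datum with BCE
positive, ranges printed older bound first. A date whose posterior would be
truncated by the curve edge is an error, not a silent truncation.

Replicate dates are pooled by inverse variance (m̄ = Σm_i/σ_i² / Σ1/σ_i²,
σ̄ = (Σ1/σ_i²)^−½) with the χ² concordance test at 5%.

Diet: collagen δ¹³C is placed linearly between −22‰ (fully terrestrial C3)
and −10‰ (fully marine) endpoints, clamped to [0, 1]; the marine fraction α
scales a full-marine reservoir age of 273 ± 18 yr, subtracted in ¹⁴C years
with the α-scaled uncertainty added in quadrature. Both endpoints and the
reservoir age are parameters of `DietModel`: regional endpoint choices vary
by a few permil in the literature, and published marine-protein estimates
for δ¹³C around −19 to −19.5‰ (≈15–20%) sit slightly below what the
−22/−10 line gives (≈19–25%), so the defaults are stated rather than
hidden. The IntCal13 curve is an optional external asset (standard
three-column layout via `read_calcurve`); all tests run on synthetic
curves, and the one test comparing against published calibrated ranges
requires the user to place `data/intcal13.14c` in the repository.

## Pipeline and I/O (`ancientkin.pipeline`, `ancientkin.io`)

SAM (plain text) is the required read interchange; coordinates are 1-based
inclusive everywhere. The pipeline runs QC → screening → sex/contamination
→ haplogroups → genotyping → IBS/MDS → admixture → calibration; stages
after screening run only for passing samples. Stage failures are recorded
in the report's status table and downstream dependents are skipped — a
partial report is always produced. Every output table carries the config
hash and seed, and re-running with an identical config is byte-identical
(no timestamps in data files). Unknown configuration keys are rejected
rather than ignored.

## Problem sizes

The test suite and acceptance script size their simulations for a single
CPU: panels of 5,000–10,000 SNPs and 45–60 individuals for MDS/admixture
recovery, 50,000 reads for damage-rate recovery, 2,000 mtDNA reads × 50
replicates per contamination level for CI-coverage studies, and 600 X
sites at ~12× for the X-contamination study. These sizes were chosen so
that Monte-Carlo error is small relative to the tolerances being checked
(e.g. ≥ 3 binomial SE margins), and they are stated here as the package's
own study conditions.

## Known limitations

- The parsimony placement and Kulczynski score are deliberate
  simplifications of likelihood placement and production mtDNA
  classifiers; their confidence values are not interchangeable with those
  tools' outputs.
- The X-contamination moment estimator assumes contaminant alleles are
  drawn at the supplied panel frequencies and is mildly biased downward at
  very low depth (the depth ≥ 2 filter mitigates, not eliminates, this).
- Admixture K selection (cross-validation) is not implemented; the K range
  is a user choice.
- No LD pruning, PCA projection, or f-statistics; no paired-end or
  UDG-treated data; no CRAM.
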