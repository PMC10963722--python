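# Methods

## The problem

Between the main Out-of-Africa dispersal (~70–60 kya) and the stable
colonisation of Eurasia (~45 kya), the ancestors of all present-day
non-Africans are thought to have persisted as a single "hub" population whose
location is unknown.  Two expansions left that hub: an earlier one carrying
the East Eurasian Core ancestry (EEC; Tianyuan, Bacho Kiro, present-day East
Asians and Oceanians) and a later one carrying the West Eurasian Core
ancestry (WEC; Kostenki14, Sunghir, later West Eurasians).  Populations whose
West Eurasian ancestry derives from a source that stayed in the hub longer
shared less drift with the Kostenki14 lineage.  `hubseek` turns that signal
into a ranking of populations by hub proximity and a map of the most likely
hub location, after removing two admixture confounders: Basal Eurasian
ancestry and EEC/WEC admixture.

## Sharing coordinates

For a reference genome R and target t, the derived-allele-sharing (DAS)
statistic is

    DAS(t, R) = #{sites: R carries ≥1 derived allele, t non-missing,
                  t carries ≥1 derived allele}
              / #{sites: R carries ≥1 derived allele, t non-missing}

computed on polarized biallelic SNPs (ancestral state = dosage 0).  A
population's coordinate is the unweighted mean over its members.  Three
references define the coordinate system: K (Kostenki14), T (Tianyuan) and U
(Ust'Ishim).  Because Ust'Ishim nearly trifurcates with the other two
lineages, all non-Basal Eurasians share a common expected U; a deficit in U
measures Basal (or African) admixture.

The denominator conditions on reference-derived, target-non-missing sites.
This makes the statistic a per-site average, so for genomes assembled from
whole-chromosome donations it is exactly the donation-weighted mean of the
donors' values — the linearity the correction algebra requires.  The
alternative convention — dividing by all non-missing sites regardless of the
reference state — multiplies every coordinate on an axis by the reference's
derived-site fraction; because each correction step is equivariant under a
common rescaling of an axis, K_B rescales by the same constant and all
downstream rankings are unchanged, so the choice is one of interpretability
(a fraction in [0, 1] conditioned on the reference) rather than substance.  For
randomly-mating admixed *diploids* the carrier predicate `dosage ≥ 1` is not
linear in ancestry fractions (it exceeds the weighted mean by
w·e·(p_WEC − p_EEC)² at each site); on pseudo-haploid data — one sampled
allele per site, the standard representation of the capture data this method
targets — the expected call is the allele frequency itself and linearity is
exact.  The simulation harness therefore represents all target cohorts
pseudo-haploid while keeping the three high-coverage references diploid.

## The correction algebra

With baselines U_mean = (U_K + U_T)/2, Basal proxy coordinates
(K_BEA, T_BEA, U_BEA), T_WEC (mean T of the >30 ky WEC genomes) and EEC
source coordinates (K_EEC, T_EEC):

1. `pBEA_X = (U_X − U_mean) / (U_BEA − U_mean)`; negative values clamp to 0.
2. `K_BR = (K_X − K_BEA·pBEA_X) / (1 − pBEA_X)`, likewise `T_BR` — the point
   X would occupy without Basal ancestry.
3. `pEEC_BR = (T_BR − T_WEC) / (T_EEC − T_WEC)`, clamped to [0, 1].
4. `K_B = (K_BR − K_EEC·pEEC_BR) / (1 − pEEC_BR)` — the K coordinate of X's
   unadmixed WEC source.  When pEEC_BR clamps to 1, X is fully EEC and K_B is
   reported undefined (the ranking skips, not sorts, such populations).
5. `pEEC_X = pEEC_BR·(1 − pBEA_X)`, `pWEC_X = (1 − pEEC_BR)·(1 − pBEA_X)`;
   the three fractions sum to 1 identically.

Each step inverts one weighted mean, so the chain is an exact algebraic
inverse of the nested-mixture construction (verified to 1e-12 on random
draws).  Clamping precedes the downstream steps, following the stated
procedure order.  Populations are ranked ascending by K_B among those with
pWEC_X ≥ 0.75 (the strictest threshold supported by the validation); ties
break stably by population label.

On real data the Basal proxy is Gumuz — an East African population without
Eurasian back-flow — used conservatively because no Basal Eurasian genome
exists; the EEC source per population is chosen by the sign of
D(ASI-proxy, Han, X, outgroup): significantly negative → Han coordinates,
positive → Onge, otherwise their average.  Baseline membership is
configuration, not code, so synthetic cohorts can substitute their own.

## D-statistics

`dstat` implements the frequency form of Patterson's D in the AdmixTools
sign convention, D ∝ Σ (p_w − p_x)(p_y − p_z), with a delete-one weighted
block jackknife (5 Mb physical blocks, ≈ the conventional 5 cM) for the
z-score.  Significance defaults to |Z| ≥ 3, the field convention — the
source publications say only "significantly".  Two screens use it: excluding
populations with African admixture (D(X, French, African, outgroup)
significantly positive) and the EEC-source assignment above.

## Focal-area inference

Sampled populations carry a value (−K_B for the hub, pBEA for the Basal
homeland) at their sampling coordinates.  For every land cell of a lon/lat
raster (default 0.5°), the shortest overland distance to each sampled
population is computed on the 8-connected land graph with great-circle edge
lengths (scipy Dijkstra); cells below sea level — adjustable by a sea-level
offset for glacial low stands — are excluded.  Cells with at least one
population within 2000 km overland get the Pearson correlation r between
their distances to all populations and the population values; the focal
area is the lowest-r region and its argmin cell.  The 2000 km rule is an
eligibility gate only (a switch restricts the correlation itself to
within-radius populations).  Coastal sampling coordinates snap to the
nearest land cell within 3 cells; farther mismatches are errors rather than
silent drops.

## The simulation harness

Demography (generation time 29.4 y, so 34 generations ≈ 1000 years;
mutation 1.25e-8, recombination 1e-8 per bp per generation):

* African population, size 14474, ancestral size 7310 before 148 kya;
* Out-of-Africa split 60 kya into a bottleneck population of 1861;
* Basal Eurasians split 57.5 kya and stay isolated (size 1861);
* EEC/WEC divergence 46 kya (the EEC expansion leaves the hub);
* ancient references branch 34 generations before their deaths:
  Ust'Ishim-like 45 kya (near-trifurcation with the divergence),
  Tianyuan-like 40 kya on the EEC branch, Kostenki14-like 38 kya on the WEC
  branch;
* WEC2 splits from the WEC stem `offset` ky before the Kostenki14-like
  branch point, so it shares exactly `offset` ky less drift with that
  lineage — the planted "closer to the hub" source;
* post-divergence sizes 1032 (WEC, WEC2) and 554 (EEC) with exponential
  growth 0.38%/0.48% per generation over the last 23 ky (`gravel_style`);
  `kamm_style` instead grows continuously from the divergence bottleneck
  (1861) to present-day sizes of ~33k/46k;
* admixed populations form 1.5 kya at size 10^4 (modern-human scale) from
  {WEC or WEC2} × EEC × Basal pulses on the composition grid
  WEC ∈ {0.25, 0.5, 0.75, 1.0} × Basal ∈ {0, 0.1, 0.2, 0.3} with EEC the
  remainder (12 valid compositions).

Sampling: 4 diploids per modern and admixed population (modern panels in the
real resource contribute up to 20 individuals; 4 keeps the within-population
standard error well below the replicate-level genealogical noise), 1 per
ancient reference.  All targets are pseudo-haploidized; references stay
diploid.

Baselines inside the simulation come from the contemporaneous unadmixed
populations (U_mean from WEC and EEC, T_WEC from WEC, the sampled Basal
population as its own proxy, the single EEC population as EEC source).  This
matters: a sharing fraction decays with the target's private drift, so an
ancient sample's U or T is systematically inflated relative to a present-day
cohort's, and ancient-sample baselines would invert the T axis at simulated
drift levels.  The correction equations themselves are unchanged.

Each replicate simulates 10 independent 5 Mb chunks, averages per-chunk DAS
values per individual, decomposes every admixed population and scores 1 when
the WEC2-sourced population's K_B is the smaller of a pair.  Averaging the
binary matrices over replicates (default 100) gives the accuracy matrix.
For the ascertainment comparison the same replicates are re-scored after
keeping only sites with minor allele frequency > 0.05 in the pooled modern
Eurasian panel (WEC, WEC2, EEC), and the paired matrices are compared by
Mantel correlation (joint row/column permutation, 999 permutations), paired
Wilcoxon and maximum cell-wise deviation.

### What desk scale does and does not show

At 10 × 5 Mb per replicate the per-replicate genealogical noise in a
population's K (sd ≈ 0.009) is of the same order as the 3 ky source signal
(ΔK ≈ 0.019), and the correction amplifies coordinate noise by roughly
1/pWEC.  Worst-case cell accuracies in the WEC ≥ 50% block therefore sit
around 0.6–0.85 at this scale, whereas genome-scale simulation (where the
noise shrinks with total sequence length) supports ≥ 0.9 everywhere in that
block.  The desk-scale run validates the machinery — unbiasedness, the null
calibration at offset 0, monotonicity in the offset — not the full
genome-scale accuracy figure; `analysis/01_ranking_validation.py
--chunk-mb` exposes the scale.  The same applies to the maximum cell-wise
deviation under ascertainment, which at 100 replicates is dominated by
binomial flip noise.

## Chimeric genomes

Chimeras are assembled by whole-chromosome donation from three diverged
sources (African-, WEC- and EEC-like, four donor individuals each — the
synthetic counterpart of the Gumuz/Sunghir/Han construction).  The default
plan walks chromosomes in descending SNP count and assigns each to the
source whose realized SNP share lags its target most, rotating donors within
a source; realized weights are recomputed from SNP counts.  The analytic
prediction for a chimera's K or T is the SNP-count-weighted mean of its
donor individuals' genome-wide coordinates, and the linearity check reports
max |empirical/analytic − 1|.

Scale matters through total genome length only: the deviation variance is
Σ_c w_c²·σ_c² with the per-chromosome spread σ_c² inversely proportional to
the number of independent gene trees.  The default simulates 22 chromosomes
of 125 Mb (mean human autosome length), each assembled from 25 independently
simulated 5 Mb pieces — statistically equivalent for this purpose (free
recombination at the joins is slightly conservative) and linear in cost
where single long chunks are quadratic.  At that scale the measured maximum
deviation is comfortably below the 0.008 bound established on real data.

## Numerical and degenerate-input choices

* Missing archaic calls never trigger site removal in archaic masking
  ("carries derived" requires observed dosage ≥ 1 in ANY listed archaic
  genome): absence of evidence must not delete data.
* A Basal proxy whose U is not below U_mean is rejected at baseline
  construction (degenerate denominator in step 1).
* Zero qualifying sites for a DAS pair raise an error naming the pair;
  per-chromosome averaging skips chromosomes with no qualifying site.
* D-statistics require ≥2 informative jackknife blocks; fewer is an error,
  not a silent Z.
* Mantel correlation is undefined (error) when either matrix is constant;
  the paired Wilcoxon returns p = 1 when the matrices are identical.
* Simulated chunks with zero segregating sites are resimulated with a
  warning (deterministically re-seeded); replicates whose sampled baselines
  are degenerate (possible only at toy scales) score as undefined cells.
* EIGENSTRAT `.geno` follows the convertf convention (count of the reference
  allele, 9 missing); pseudo-haploid samples are written 0/2.

## Known limitations

* The synthetic cohorts contain no archaic introgression, no missing data,
  no sequencing error and a uniform recombination rate; tests passing on
  them validate the estimators and algebra, not robustness to those
  real-data features (archaic confounding is handled upstream by masking).
* The palaeoecological layer of the original study (species distribution
  models, carrying capacity) is out of scope; the landmask here is
  elevation-plus-offset only.
* K_B is a point estimate; no uncertainty is propagated through the
  correction chain.
* The focal surface treats sampled populations as exchangeable points; no
  spatial autocorrelation correction is applied to the per-cell Pearson r.
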