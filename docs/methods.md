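# Methods

This document records the statistical model, the simulation design, the
numerical choices and the known limitations of the implementation.

## 1. Meiosis and population model

Autotetraploid (ploidy 4 by default; any even ploidy is supported in the
core routines). Meiosis is strictly **bivalent**: the homologs are paired
into ploidy/2 bivalents drawn uniformly from all perfect matchings (3 for
ploidy 4), each bivalent transmits exactly one chromatid, and the
transmitted chromatid's parental origin starts at either homolog with
probability ½ and switches at crossover points from a Poisson process at 1
crossover per 100 cM (Haldane model: no interference). Double reduction is
excluded.

Consequences used throughout:

* The transmitted gamete dosage for a parent of dosage `d` is
  hypergeometric: choose ploidy/2 of the ploidy homologs uniformly. The
  offspring dosage distribution for parental dosages `(d1, d2)` is the
  convolution of the two gamete distributions — e.g. 1:1 (SN), 1:4:1
  (DN), 1:8:18:8:1 (DD), 1:5:5:1 (SD) in a tetraploid.
* For a marker pair, homolog labels are exchangeable, so the joint
  two-locus gamete distribution of one parent depends on the phase only
  through the overlap count `m = |S_A ∩ S_B|` of the allele-carrying
  homolog sets.
* Between two loci at map distance `d`, each bivalent's transmitted
  chromatid switches homolog with probability `r = (1 − e^(−d/50))/2`,
  independently across bivalents given the matching.

The default simulated design is one 100 cM chromosome carrying the five
segregation types SN, SS, SD, DN, DD co-located at every 1 cM position
(505 markers) in a population of 200 F1 individuals plus the two parents.
Phases (which homologs carry the allele) are drawn uniformly per marker
and parent.

## 2. Observation models

**Array signal ratios.** The expected counted-allele signal fraction for
dosage `d` is `xi = f / (h(1−f) + f)` with `f = d/ploidy` and allelic bias
`h`. Observed ratios are Beta-distributed with mean `xi` and intra-class
correlation `rho` ("overdispersion"); `rho = 0` returns the exact class
means. Boundary classes are offset by 1e-4 to keep the Beta parameters
positive.

**Sequencing read counts.** The per-read probability of the counted allele
is `p = xi(1−eps) + (1−xi)eps` with sequencing error `eps`; the
counted-allele read count out of the depth is beta-binomial with
intra-class correlation `rho` (binomial at `rho = 0`). Depth is fixed or
uniform on an integer range.

## 3. Dosage calling

**Reads.** Class log-likelihoods are beta-binomial per candidate dosage.
In the simulation studies the caller is given the generating `eps`, `h`
and `rho` (a deliberate design decision: the studies isolate the effect of
genotype uncertainty on mapping, not of noise-parameter estimation).

**Arrays.** Per marker a (ploidy+1)-component normal mixture is fitted by
EM on arcsine-square-root transformed ratios, with class means tethered to
their theoretical positions and a shared standard deviation. Markers whose
fit fails to converge or collapses are flagged and excluded downstream.

**Joint F1 family model.** In an F1 design, the two parental samples alone
rarely determine the parental dosages confidently, yet those dosages set
the segregation prior for every offspring. The family caller treats the
parental dosage pair `(d1, d2)` as a latent variable with a uniform prior
over all (ploidy+1)² combinations; each combination's likelihood is the
product of the parents' class likelihoods and every offspring's
segregation-mixture likelihood `Σ_k seg_k(d1,d2) · lik_k`. Parent
posteriors are marginals of the combination posterior; offspring
posteriors are the combination-weighted mixture posteriors. This is the
standard family-aware calling approach for F1 designs and applies to both
channels (for arrays, the fitted class densities feed the same model).

## 4. QC and curation

* Duplicate individuals: merged when the correlation of posterior-weighted
  dosage vectors exceeds 0.95 (group posteriors averaged, renormalised).
* Poorly scored individuals: flagged when fewer than half their markers
  reach a maximum posterior of 0.6.
* Segregation typing: parental dosages must reach posterior confidence
  0.9; a chi-square statistic compares probabilistic class totals with the
  expected ratios (p ≥ 1e-3), mass on impossible classes is capped at
  0.05, and the parental type must be among the best candidates under a
  multinomial model over all segregation types. Matching markers are
  converted to *simplest form* (dosages reflected so the counted allele is
  the minority allele) before linkage.

## 5. Two-point linkage

The expected joint offspring table `E(n_ij | r)` is computed by exact
enumeration over bivalent matchings and stored as polynomial coefficients
in `r` (degree ≤ ploidy/2 per parent), so a likelihood evaluation is a
polynomial evaluation plus a tensor contraction.

* Discrete likelihood: `Σ_ij O(n_ij) log E(n_ij)` over non-missing pairs.
* Probabilistic likelihood: `Σ_z log Σ_ij P_z(i)P_z(j) E(n_ij)`; the joint
  genotype probability is the product of the two per-locus posteriors
  (calling noise independent across loci). On one-hot posteriors this
  reduces *exactly* to the discrete form (verified in the acceptance
  suite).

For each admissible phase pair `(m1, m2)` the likelihood is maximised over
`r ∈ [0, 0.5]` (coarse grid to rank phases, then bounded Brent on the two
leaders; ties broken toward coupling). `LOD = log10 L(r̂) − log10 L(0.5)`
uses the same phase's likelihood at `r = 0.5`, because under the bivalent
model the likelihood at `r = 0.5` is *not* phase-invariant for pairs that
are multiplex in the same parent (the shared matching induces residual
dependence); for simplex pairs the invariance holds.

## 6. Map construction

1. Simplex×nulliplex markers of each parent are clustered into homolog
   candidates by coupling-phase linkage at LOD ≥ 5 (connected components).
2. Remaining markers join, per parent, the `d` clusters with the strongest
   coupling support at LOD ≥ 3.
3. Pairwise Haldane distances (recombination fractions clamped at 0.4999)
   enter a **LOD²-weighted SMACOF** metric MDS in 2D; marker positions are
   arc lengths along a principal curve (lowess smoothing, span 0.3)
   through the configuration; a 1D embedding is available as a fallback.
4. Positions are rescaled so map distances regress 1:1 on the observed
   pairwise distances (weighted least squares over all pairs).
5. **NNfit pass**: for each marker, the absolute difference between the
   observed distance to its nearest *informative* neighbour (LOD ≥ 3,
   nearest on the map) and the map-implied distance; markers exceeding
   5 cM are removed and the remainder re-ordered once. Restricting to
   informative neighbours prevents weakly informative co-located pairs
   (whose r̂ is noisy by construction) from flagging sound markers.

## 7. Numerical choices

* All expected tables are cached per (segregation types, phase, ploidy) as
  polynomial coefficient tensors; likelihood curves over a grid evaluate
  all phases in one einsum.
* Posterior arithmetic is done in log space with max-subtraction;
  zero-depth read cells carry log-likelihood 0 (no information).
* The SMACOF embedding starts from classical MDS scaling and uses the
  pseudo-inverse of the weight Laplacian; it is deterministic.
* Random draws all flow from `numpy.random.default_rng` seeded explicitly;
  every pipeline stage is reproducible bit-for-bit from its seed.

## 8. Limitations and honest deviations

* **Noise parameters are known to the caller** in the simulation studies.
  Real callers estimate `eps`, `h`, `rho` per marker and are accordingly
  less sharp. Two published reference points are therefore not matched:
  accuracy at 60× with overdispersion 0.06 comes out ≈87% here versus a
  published 82.1%, and marker retention after discretising at threshold
  0.85 / missing 0.15 at 40× comes out ≈90% versus a published 62.5%.
  Both deviations are in the direction "sharper posteriors than the
  reference caller" and disappear only if parameter estimation noise is
  added deliberately, which the study design here avoids.
* **Map-position regression slopes sit below 1** (≈0.85 at full scale on
  read data) whereas the published reference maps are *expanded* (slopes
  1.05–1.11). The published expansion is driven by caller noise inflating
  short-range r̂ estimates, which the exact-likelihood, known-parameter
  setting here does not produce; in addition, LOD² ordering weights
  slightly compress the metric, because at fixed true r a pair whose r̂
  fluctuates low realises a higher LOD and hence more weight. Repulsion
  pairs do show the upward short-range bias that expands unweighted maps,
  but LOD² weighting suppresses exactly those pairs. The weight exponent
  is kept at LOD² deliberately; slopes approach 1 as the exponent is
  lowered, but changing it would be tuning.
* The array caller is a deliberately simple normal-mixture EM; markers at
  high overdispersion (ρ ≥ 0.03) increasingly fail its convergence checks
  (~84% retained at ρ = 0.03), which mirrors the behaviour of reference
  array callers only qualitatively.
* The meiosis model excludes quadrivalents and double reduction; the
  segregation table for SD markers is the derived 1:5:5:1 (exact under
  random bivalent pairing).
* Multi-chromosome designs are out of scope: a single linkage group is
  simulated and mapped (clustering into linkage groups would precede this
  pipeline in practice).
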