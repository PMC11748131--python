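# Methods

Statistical and numerical methodology of `evoconverge`, module by module,
with parameter defaults and their rationale. Coordinates are 1-based
inclusive internally; bedGraph I/O converts to/from 0-based half-open.

## Variant curation (`curation`)

Raw polymorphism calls (a breseq-genome-diff-like TSV) pass through five
rules in a fixed, reported order:

1. **Reference discrepancies** — calls at loci that were already at 100%
   frequency when the *ancestor* was re-assembled against the reference.
   They are reference errors, not evolution; removed unconditionally.
2. **Heterozygous loci** — loci at intermediate frequency in the ancestral
   re-assembly. An evolved call there is kept only when fixed
   (frequency ≥ `fixed_threshold`, default 0.99): fixation is a real
   loss-of-heterozygosity event, anything else is standing variation.
3. **Low coverage** — calls at positions with depth < `min_depth`
   (default 5); the boundary is kept.
4. **Ancestral** — calls keyed by (element, position, alt, type) present in
   100% of the organism's replicate lineages predate the experiment.
   Requires ≥ 2 lineages; applied after the per-call rules so that a
   removed artifact cannot mask universality.
5. **Frequency cutoff** — calls below `freq_cutoff` (default 0.05) are
   dropped; the boundary survives.

The chain is idempotent when the ancestral rule is excluded; the ancestral
rule itself is not (removing calls can change who "all lineages" are), which
is why `curate` runs it exactly once.

## Codon-aware classification (`codon`)

SNPs inside coding genes are classified synonymous / nonsynonymous /
nonsense / stop-loss by mutating the affected codon and translating
(NCBI genetic codes via Biopython; standard code by default). Minus-strand
genes have forward-strand alleles complemented before lookup; a mismatch
between the call's reference allele and the CDS raises instead of guessing.

**Site counting** is Nei–Gojobori-style: for every codon position, the
synonymous site share is (number of the 3 possible substitutions that are
synonymous)/3, so syn + nonsyn sites sum exactly to CDS length. Stop codons'
substitutions count as non-synonymous (stop-loss changes the protein).

**Neutral expectations.** Under a uniform substitution model each base has
one transition and two transversion partners, so ts:tv = 0.5; a
`kappa`-weighted model shifts it to κ/2. The expected nonsense fraction is
the weighted share of all possible coding substitutions that turn a
non-stop codon into a stop, computed by enumeration over the actual genome
(it depends on codon usage; ≈ 4% for the synthetic genomes here).

## Selection metrics (`selection`)

* **dN/dS (pN/pS):** (N/nonsyn sites)/(S/syn sites), pooling nonsynonymous,
  nonsense and stop-loss in the numerator (all protein-changing). ≈1 under
  neutrality by construction. Undefined (None) when S = 0 unless the
  Haldane–Anscombe +0.5 pseudocount is requested.
* **ts:tv** from (ref, alt) pairs; compare to the model expectation.
* **Nonsense ratio:** observed nonsense fraction / expected fraction; ≈1
  neutrally, < 1 under purifying selection against truncations.
* **Group comparison:** per-lineage metrics are compared by a group-means
  OLS model (`metric ~ C(group) - 1`), giving per-group 95% CIs, flags for
  CIs excluding the neutral value, and unadjusted pairwise contrasts.
  Groups with < 2 defined values are omitted, not imputed.

## Convergence screen (`convergence`)

Mutations are binned to genes (coding hit, or ≤ 50 bp upstream promoter
window for intergenic calls; a coding assignment beats an overlapping
neighbour's promoter). Qualifying classes for the screen are
nonsynonymous + nonsense + promoter + indel (prokaryote mode) or
nonsynonymous + nonsense only (eukaryote mode, which also drops non-coding
calls at the binning step).

**Null model.** For a lineage with *n* observed qualifying mutations over a
coding genome of *g* bp, each gene of length *l* receives
Poisson(λ = n·l/g) mutations per randomized trial; 100 trials (matrices)
are drawn per screen. Using each lineage's own total preserves
between-lineage load differences.

**Calling criteria.** A gene is called when
(i) its observed cross-lineage sum strictly exceeds the maximum per-gene
sum over all randomized trials, **or**
(ii) it is hit in ≥ 50% of eligible lineages (prevalence);
and it is **not** vetoed by meeting either criterion on the synonymous
table. Hotspots elevate synonymous and nonsynonymous rates alike, so the
veto separates mutation-rate artifacts from selection. The screen runs per
treatment, so genes can be treatment-specific or shared.

Calibration at study scale (2 × 6 lineages, 2000 genes, ~100
mutations/lineage): on pure-null data criterion (i) fires in < 1% of genomes
per treatment (the observed labelling is one exchangeable draw among the
101; strict inequality breaks ties against calling), and the final-call
per-gene false-positive rate — essentially criterion (ii) chance
co-occurrence — is ≈ 0.1%, well under 1%.

**ECDF tests.** Observed and randomized per-gene count distributions are
compared by the KS sup-distance (tie-aware: evaluated at tie-block ends)
and a variance-weighted integrated distance
DTS = Σ |Fₓ−F_y| · Δz / √(F̄(1−F̄)), which up-weights tail discrepancies.
Both get label-permutation p-values, vectorized over permutations. The
default estimate (1 + #{T ≥ T_obs})/(B+1) is valid but conservative for
discrete statistics; `tie_break="random"` uses the randomized rank
p = (#{T > T_obs} + U·(#{T = T_obs}+1))/(B+1), exactly uniform under
exchangeability — use it when calibration matters, the default when a
conservative decision rule is preferred.

**Per-gene treatment test** (`gene_treatment_test`): pooled-variance
two-sample t-test per gene, vectorized; constant genes get p = 1.
**ORA** (`enrichment_ora`): hypergeometric upper tail with
Benjamini–Hochberg adjustment across sets.

## Co-occurrence network (`network`)

Counts collapse to presence/absence per gene × lineage. Genes with
prevalence outside [0.5, 0.9] are dropped (always- or never-mutated genes
carry no association signal). Each pair gets Spearman ρ of the binary
vectors and an odds ratio (+0.5 to all cells when any is zero). Edges form
where ρ falls in [0.5, 0.9] (co-occurrence) or [−0.3, −0.2] (avoidance),
both windows closed — the upper positive bound excludes near-perfectly
collinear pairs that are likely linked rather than interacting. Direction
points from the gene whose presence better predicts the other
(max conditional probability). Output is a networkx DiGraph plus an
in/out-degree table; GraphML and TSV exporters included.

## Copy number (`copynumber`)

Copy number of a plasmid region = region mean depth / chromosome mean depth
in the same lineage (ratios cancel run-to-run depth scale). Loss is a
ratio < 0.01 (strict); a breadth-of-coverage variant is provided for
degraded samples. Three canonical diagnostic windows (insertable
170–180 kb, full plasmid 120–130 kb, reduced 40–50 kb) capture the distinct
behaviours of an integrating, a free, and a reduced plasmid form.
Duplications are maximal runs of depth ≥ 5× the element mean (`fold` mode)
or ≥ mean + 5 SD (`sd` mode, for low, noisy coverage), merged across ≤ 100
bp gaps and filtered to runs overlapping a CDS or promoter window.
Group differences use exact two-sided Mann–Whitney tests (the asymptotic
tie-corrected approximation is unreliable at a handful of lineages) with
Holm adjustment; loss-versus-partner contingency uses Fisher's exact test.

## Growth (`growth`)

Serial batch transfer with dilution factor D = final/transfer volume
(0.5 ml → 13 ml gives 26) supports log₂ D ≈ 4.7 generations per transfer.
Media nitrogen at Redfield stoichiometry is 16 × phosphorus (2 µM P →
32 µM N).

* **RGR** (realized growth rate, per day): ln(N_final/N_initial)/Δt over a
  whole transfer window, N_initial = previous window's final density / D.
  Captures lag and die-off; a steady-state culture diluted D-fold every T
  days must show RGR = ln(D)/T.
* **EGR** (exponential growth rate): slope of the best contiguous
  log-linear window of ≥ max(3, ⌈n/2⌉) points maximising R²; ties prefer
  longer, then earlier windows.
* **Filtering:** 5% two-tailed trim of RGR within each stratum
  (treatment × transfer by default); EGR fits with R² < 0.95 are masked
  (boundary kept). Trimming is not idempotent — apply once.
* **Evolutionary rate:** OLS of rate on generation; the normalized rate is
  slope/intercept (per generation, intercept = estimated ancestral rate)
  with a delta-method 95% CI from the OLS (co)variances. Requires ≥ 5
  defined transfers; a non-positive intercept leaves it undefined rather
  than reporting a sign-flipped ratio.

## Synthetic data (`simulate`)

The generator produces, from one master seed (independent per-stage
`SeedSequence` spawns, so changing growth noise never perturbs the genome):

* a reference genome of `n_genes` (default 2000) genes, lognormal lengths
  (median ≈ 800 bp, clipped to [150, 3999], rounded to codons), alternating
  strands, 120 bp spacers (upstream promoter windows never overlap coding
  sequence), ATG…stop CDSs with no internal stops;
* per-lineage mutations for 2 treatments ("400", "800") × 6 replicates:
  ~100 Poisson background mutations placed by length (10% intergenic), 70%
  at U(0.05, 0.5) frequency and 30% fixed; **planted truth** — 5 convergent
  genes (fixed nonsynonymous SNPs in 4 of 6 lineages of one treatment),
  3 syn+nonsyn hotspots (5 of 6 lineages, both treatments), 20 ancestral
  variants in all lineages, 10 reference discrepancies, 30 heterozygous
  loci fixing with probability 0.3 per lineage;
* Poisson depth-of-coverage tracks (100× chromosome) with per-lineage
  plasmid copy number/retention truth and optional duplications;
* serial-transfer growth series: within transfer k the rate is
  ancestral + slope·(k·log₂ D) + N(0, σ), densities sampled every 48 h and
  diluted 26-fold at the cutoff crossing.

Every emitted variant carries a truth label (de_novo, planted_convergent,
hotspot, ancestral, reference_discrepancy, het_fixed, het_nonfixed), and
every gene a gene-level label, enabling exact sensitivity/FPR measurement.

Scope and limitations: mutations are placed independently (no linkage or
clonal interference), coverage is Poisson (no GC or mappability bias),
growth is deterministic exponential within a transfer with rate noise only,
and frequencies do not evolve over time. These idealizations are deliberate:
the generator validates the *inference* machinery, not population-genetic
dynamics.

## Numerical choices

* All stochastic APIs accept explicit `numpy.random.Generator`s;
  module-level seeds fan out via `SeedSequence` spawns.
* Permutation tests are vectorized (cumulative-sum ECDFs over a permuted
  label matrix) rather than looped.
* Mergesort (stable) ordering wherever ties must be deterministic.
* Exact tests (Mann–Whitney, Fisher, hypergeometric) at small n; asymptotic
  only where exactness is impossible or irrelevant.
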