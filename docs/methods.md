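# Methods

This note documents the statistical procedures implemented in `acidonet`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical edge cases and known limitations.

## The setting

Soil surveys along a wide pH gradient repeatedly find that weakly acidic
soils favour a slow-growing complete ammonia oxidizer (comammox
*Nitrospira*): its abundance and activity fall with pH, it sits among the
core genera, it occupies a connector position in co-occurrence networks, its
removal in silico collapses a disproportionate share of the network, and its
genome is one of very few carrying the complete cobalamin biosynthesis
pathway in a community where most genomes depend on cobalamin. `acidonet`
packages the analysis chain behind those observations so that each step can
be tested against planted ground truth.

## Synthetic surveys (`simulate`)

One `CommunitySpec` describes a survey. Defaults mirror the emulated design:
36 samples spread evenly over pH 4.4–9.7 and grouped A (pH < 6.5),
B (6.5 ≤ pH ≤ 7.5), C (pH > 7.5); 100 taxa; 20 000 reads per sample; 16 SIP
density fractions over 1.69–1.76 g/mL. Every artifact draws from a labelled
child stream of the master seed (`SeedSequence([seed, crc32(label)])`), so
adding one output never perturbs another, and identical spec + seed gives
byte-identical outputs.

**Community model.** Latent log-abundance of taxon *i* in sample *s* is
`baseline_i + loading_i * (pH_s − mean pH) + noise` with loadings
N(0, 0.1²·pH-unit⁻²). The keystone's loading is solved analytically so its
latent correlation with pH equals `keystone_ph_slope` (default −0.6); the
realized Pearson r on relative abundances averages ≈ −0.59 across seeds.
Counts are multinomial over the per-sample softmax, so column sums equal the
sequencing depth exactly and all downstream analyses face real compositional
closure.

**Cooperation block.** Twelve taxa load on the keystone's own latent signal
with a target pairwise correlation of 0.70. This number matters: block–block
correlations are then ≈ 0.70² ≈ 0.49 while block–keystone correlations are
≈ 0.70, so at the default network threshold (0.60) block members connect to
the community *only through the keystone*. That dependence — not mere
co-occurrence — is what makes the keystone's removal collapse the network.
Block taxa inherit the keystone's pH trend, as a cooperating guild around an
acid-favoured taxon should.

**Growth strategy.** The keystone and its block carry one rrn operon (the
*Nitrospira* trait); other taxa get `3 + 2·(loading/σ_loading)` copies plus
jitter, clipped to [1, 15], so acid-favoured taxa are slow growers and the
community mean copy number (MCN) rises with pH.

**Guild qPCR table.** log₁₀ amoA copies/g for AOA (7.0), AOB (6.6) and
comammox (7.6 at pH 6.5, slope −0.5 log₁₀/pH unit). When the community table
is supplied, the comammox column also inherits the keystone's pH-orthogonal
abundance residual — qPCR of a guild marker measures the same DNA extract
the community table describes — with residual noise 0.1 log₁₀. The defaults
place the comammox/AOA crossover near pH 7.7, so comammox dominates ≈ 62% of
samples along the gradient.

**Genomes.** 150 genomes; P(≥1 dependence gene) = 0.85; full
synthesis-pathway prevalence 0.03 besides the keystone genome (always
complete, labelled `comammox`); 12% carry only steps B+C. Abundances are a
genome-specific lognormal level (σ = 1.0) times per-sample jitter (σ = 0.2) —
MAG coverages are strongly autocorrelated across samples — normalized so the
keystone genome's abundance equals the keystone taxon's relative abundance.
The jitter value calibrates the planted supplier-share/pH association to the
strength the design emulates (realized mean r ≈ −0.58).

**SIP.** Copies per fraction follow a discretized Gaussian over buoyant
density (centre 1.715 g/mL, σ = 0.012) with Poisson counting noise;
¹³C-labelled profiles of active guilds (default comammox and AOA) shift
heavier by `planted_shift` (default 0.010 g/mL). Guild amplitudes 60k/25k/15k
(comammox/AOA/AOB) set the heavy-window composition.

**What the generator does not emulate:** read-level errors, chimeras,
taxonomy noise, phylogenetic signal, spatial autocorrelation between
samples, or depth variation across samples. Passing recovery tests therefore
demonstrates that the estimators detect planted effects through
compositional and counting noise — not that they are robust to field
sampling artifacts.

## Networks (`network`)

Taxa present in < 50% of samples are dropped; correlations are Pearson on
log relative abundances with zeros replaced by half the smallest nonzero
relative abundance (scale-stable; correlations are invariant to constant
multiples). Constant taxa get zero correlations and a flag.

**RMT threshold.** For each t in 0.30…0.99 (step 0.01) the |r| matrix is
thresholded, nodes without surviving off-diagonal entries are removed, and
the eigenvalue spectrum is unfolded by fitting a degree-≤10 polynomial to the
cumulative eigenvalue staircase (near-degenerate eigenvalues collapsed
first). Nearest-neighbour spacings are tested against Poisson e⁻ˢ and the
GOE Wigner surmise by chi-square on ten equal-probability bins; the selected
threshold is the smallest t whose spacings are Poisson-consistent
(p > 0.05). Matrices under 30×30 fall back to a fixed threshold with a
warning; if no t qualifies, the grid maximum is returned with a
`no-transition` flag (e.g., an identity matrix). On constructed
block-diagonal matrices with a magnitude gap between within-block and
between-block entries, the selected threshold falls inside the gap; on
unthresholded noise-data correlation matrices the spacings are closer to
Wigner–Dyson, as RMT predicts. Whether to threshold signed or absolute r is
not decidable from the emulated pipeline; |r| is used.

**Thresholds in practice.** The RMT transition tracks where cross-module
edges thin out, so on data with a *continuum* of correlation strengths the
selected value drifts with generator structure. The recovery studies
therefore fix the build threshold at the `CommunitySpec.network_threshold`
default (0.60, within the range RMT selection typically returns for surveys
of this shape); auto-selection remains available everywhere
(`select_rmt_threshold`) and is exercised on constructed matrices where its
behaviour is provable.

**Modules and roles.** Greedy modularity maximization on |r| weights
(deterministic; components never share modules), modularity Q reported.
Zi–Pi use unweighted degrees per the original hub/connector formulation;
Zi = 0 where a module's within-degree spread is zero. Roles: Zi ≥ 2.5 →
module hub; Pi ≥ 0.62 → connector; both → network hub; a node is a *key
node* if either holds.

## Cohesion (`cohesion`)

For each ordered pair (i, j), the null correlation is between observed row i
and row j permuted across samples ("taxa shuffle"); the corrected
correlation is the observed Pearson r minus the null mean over `n_iter`
(default 200) iterations, symmetrized by averaging the two directions. A
taxon's positive/negative connectedness is the mean of its strictly
positive/negative corrected correlations; a sample's positive/negative
cohesion is the abundance-weighted sum. `cohesion_net = C₊ + C₋` (signed)
and `cohesion_total = C₊ + |C₋|` are both reported. Cohesion is computed on
the full relative table by default (not the prevalence-filtered one); both
options exist.

**Calibration and an intrinsic offset.** On tables whose taxa are genuinely
independent (rows shuffled), the net-cohesion median is close to — but not
exactly — zero, for two measurable reasons: (i) compositional closure forces
the average pairwise correlation toward −1/(n_taxa − 1), which the taxa
shuffle null does not see; (ii) the null distribution of Pearson r between
rows with shared marginal skew is itself right-skewed, which offsets the
positive/negative split even after the null mean is removed (and flips sign
under a log transform, where counting noise skews left). At the calibration
settings (100 taxa, 40 samples, moderately even abundances) the net offset
is ~+0.003, i.e. ≈ 2% of the cohesion magnitude and *below the Monte-Carlo
resolution of a single calibration replicate* (between-replicate SD of the
median ≈ 0.002–0.003); heavy-tailed communities (lognormal σ = 1) show a
larger skew term (~+0.02). The calibration study uses moderately even null
communities so it measures estimator behaviour rather than the data-skew
term, and reports the per-replicate medians with their Monte-Carlo SD so the
offset is visible rather than hidden. Interpret small absolute differences
in net cohesion accordingly; contrasts and correlations of cohesion across
samples, which share any offset, are unaffected.

## Robustness (`robustness`)

wMISᵢ = Σⱼ bⱼ·sᵢⱼ / Σⱼ bⱼ over currently surviving neighbours, with bⱼ the
mean relative abundance across samples (a per-group abundance vector can be
substituted) and sᵢⱼ the signed edge correlation. Extinction (wMIS ≤ 0, or
no surviving neighbour — "extinct or isolated") is applied synchronously and
iterated to a fixed point; a single-sweep mode exists. The fixed point
matches exhaustive enumeration on small graphs and is invariant to node
relabelling.

Removal experiments start from the **equilibrium network**: the fixed point
of the empty-target cascade. A mixed-sign network loses a sizeable share of
nodes to baseline pruning; starting both targeted and random removals from
the same pruned equilibrium isolates the *marginal* effect of the removed
node instead of re-measuring the baseline collapse, and removes the
paradoxical "rescue" effect whereby deleting a node's negative edges during
the baseline collapse spares its antagonists.

## Screens (`screen`)

- **Rarefaction** is exact multivariate hypergeometric sampling per sample
  (columns sum exactly to depth; marginal expectations equal
  depth·count/total); shallower samples are dropped with a warning.
- **Core genera**: ubiquitous (> 80% of samples), overall abundant (mean
  relative abundance > 0.1% by default; a top-quantile mode exists because
  the two published wordings of this rule disagree), and frequently abundant
  — rank within the top 80% of genera, while detected, in > 50% of samples
  (the rank-quantile reading; the percentage-abundance reading is internally
  inconsistent). All three flags are returned per genus.
- **Candidate (PC) taxa**: within an externally supplied lineage set, taxa
  whose relative abundance correlates with a marker-gene vector at
  r ≥ r_min (default 0.5) and p ≤ 0.05. qPCR markers should be supplied on
  the log scale, as is standard for copy-number data.
- **Dominant oxidizer**: argmax of guild copies with shares; exact ties are
  broken alphabetically and flagged; all-zero samples are flagged
  unclassifiable.
- **rrn/MCN**: lookup matches species, then genus, then family; unmatched
  taxa are excluded and counted. MCN divides by matched abundance mass by
  default (unmatched taxa otherwise bias the mean toward zero); raw
  weighting is available since the emulated pipeline does not state which
  was used.

## Cobalamin (`cobalamin`)

CD = any of *mutA*, *metH*, *rsmB*; CS = steps A, B and C all complete (step
completeness is an input boolean — mapping annotation output to steps is the
caller's concern, keeping the module annotation-tool-agnostic). Per-sample
summaries weight by genome relative abundance; the supplier share divides
comammox-labelled CS abundance by total CS abundance (NaN and flagged where
a sample has no CS abundance). The same operation serves contig-level
tables. `gene_set_tpm` validates that TPM columns total 10⁶ within 1%.

## Environmental statistics (`envstats`)

- `correlate`: Pearson (or Spearman) with two-sided p and Fisher-z 95% CI;
  degenerate inputs raise. Empirical type-I error is checked at ~5%.
- `variance_partition`: commonality analysis over ≤ 3 predictors. Unique
  ("Individual") fraction of X = adjR²(full) − adjR²(full minus X); shared
  fractions by inclusion–exclusion; residual = 1 − adjR²(full); the
  fractions reconstruct adjR²(full) exactly. Adjusted R² is the default
  (common ecology practice); note adjusted fractions of orthogonal
  predictors are only approximately zero because the small-sample penalty is
  not additive — raw-R² mode (`adjusted=False`) restores exact zeros.
  Near-collinear designs (condition number > 1e8) warn but report.
- `free_ammonia`: NH₃ = TAN / (1 + 10^(pKa − pH)), pKa(T) = 0.09018 +
  2729.92/T_K (Emerson 1975). Mass balance NH₃ + NH₄⁺ = TAN holds exactly;
  at pH = pKa exactly half the TAN is NH₃. Unit conversion to molar TAN is
  the caller's responsibility.
- `nitrification_rate`: OLS slope of the NO₂⁻+NO₃⁻ series against time with
  fit R²; ≥ 3 distinct time points required.

## DNA-SIP (`sip`)

Profiles are ordered (density, copies) vectors (≥ 10 fractions, strictly
increasing density). Normalized shares sum to 1 and the total supports the
labelled-vs-control total check. The label shift is
WMD(¹³C) − WMD(¹²C) with WMD the copies-weighted mean density; profiles on
different grids are linearly interpolated onto their overlap (fractions are
approximately evenly spaced in density, so linear interpolation is
adequate). A guild is called labelled when the shift reaches `min_shift`
(default 0.005 g/mL, half the default planted shift; at typical copy
numbers Poisson noise moves the WMD by ≪ 1 mg/mL, giving essentially full
power). The heavy window defaults to 1.72–1.75 g/mL — the published analyses
identify heavy fractions visually, so the window is a configurable interval —
and guild shares inside it are normalized to sum to 1.

## Study drivers (`studies`)

`recovery_study` runs the full pipeline over independent seeds and reports,
per survey: the keystone–pH correlation, the MCN–pH correlation, the
positive-cohesion–keystone correlation, targeted-vs-random surviving
fractions from the equilibrium network, the supplier-share–pH correlation,
and SIP label detection. `cohesion_null_calibration` and
`correlate_type1_error` implement the null checks described above. The
problem sizes (50 surveys of 36 samples × 100 taxa; 200 null iterations;
1000 type-I replicates) keep a full run around a minute on one CPU while
holding the binomial noise on the reported rates near ±4 percentage points.

## Known limitations

- Cohesion's null median carries the small intrinsic offset analysed above;
  it is a property of the pos/neg split of null-corrected Pearson
  correlations on compositional data, not of this implementation.
- The RMT criterion assumes enough eigenvalues for spacing statistics
  (≥ ~50 spacings after unfolding); small or nearly empty matrices fall back
  or flag `no-transition`.
- Network links are taken at face value: no decomposition of direct vs
  indirect associations and no environmental-filtering test is included, so
  edges mix interaction and shared-response signal (the keystone's negative
  edges to alkaline-adapted taxa in full-gradient networks are exactly such
  shared-response links).
- Cascade abundances are fixed at pre-removal means; no regrowth or
  rewiring.
- The generator's taxonomy strings are structural placeholders without
  phylogenetic signal; `assign_rrn` provenance logic is exercised, but real
  rrndb matching subtleties (synonyms, rank gaps) are out of scope.
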