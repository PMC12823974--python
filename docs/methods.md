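# Methods

`npcoupling` implements an inference chain from amplicon count tables (16S
bacteria, ITS fungi, phoD-harboring bacteria) and seven soil nutrient-cycling
variables to (i) N-P coupled vs decoupled site labels, (ii) coupled vs
decoupled taxon labels, and (iii) paired signed co-occurrence networks with
topology metrics and composite-score keystone taxa. This note records the
model, the defaults, and the design choices that were genuinely open.

## Site classification

A site is **coupled** when both stoichiometric ratios clear their thresholds
strictly: TN/TP > 3 and net N mineralization / available P (net_Nmin/AP)
> 0.16. Both thresholds are configurable; the defaults are the
field-calibrated values for the subtropical pine-forest system this method
targets and are system-specific, not universal. TP and AP must be positive
(the ratios are otherwise undefined); net_Nmin is a 28-day net change and may
legitimately be ≤ 0 — only the comparison with the threshold is used.

## Preprocessing

The stage order is fixed and each filter is idempotent:

1. **Global abundance floor** — features contributing strictly less than
   0.001% (`global_floor = 1e-5`) of all reads in the table are removed; a
   feature exactly at the floor is retained.
2. **Averaged rarefaction** — target depth D = floor(0.9 × minimum site
   depth). Each of 100 repetitions draws D reads per site *without
   replacement* (multivariate hypergeometric), and cells are averaged across
   repetitions, so every site's row sum equals D exactly and cell means
   converge to D × (count / site total). The seed is split per repetition;
   results do not depend on repetition order.
3. **Retention** — 16S and phoD features must occur in at least
   ceil(10% × n_sites) sites (rounded **up**: 4 of 35); ITS features must
   carry at least 10 reads in total. Occurrence means abundance > 0 after
   rarefaction averaging, and the rule is applied after rarefaction,
   following the stage listing order.
4. **Aggregation** — features are summed into phyla or genera via the
   taxonomy map (placeholders aggregate under their `unclassified_<parent>`
   name) and converted to relative abundance *within each marker group*,
   since the three assays are separate sequencing universes.
5. **Major taxa** — taxa whose **mean** relative abundance across sites is
   strictly above 0.1% are kept. Whether the 0.1% cutoff should be on the
   mean, the maximum, or any single sample is not standardized; the mean is
   used here and the cutoff is configurable.

## Taxon coupling labels

For each marker group and rank, every retained taxon is correlated (Pearson)
with the seven variables — four N-cycling (TN, NAG, net_Nmin, N_inorg) and
three P-cycling (TP, AP, AKP) — with two-sided p-values and **Bonferroni**
adjustment. The adjustment family is all computable taxon × variable tests
within one (marker group, rank) analysis; a per-taxon family (m = 7) is
available as a sensitivity mode. Constant vectors are flagged non-computable
and excluded from the family size. Labels partition the taxa:

| label | rule (on adjusted p < 0.05) |
|---|---|
| coupled_positive / coupled_negative | significant with ≥ 1 N- and ≥ 1 P-variable, all significant r sharing one sign |
| decoupled_N / decoupled_P | significant in exactly one family |
| inconsistent | significant in both families with mixed signs |
| none | no significant correlation |

The "inconsistent" category is this package's own convention: mixed-sign
dual-family taxa fit neither the coupled definition (which demands sign
consistency) nor the decoupled one, so they get a dedicated label rather
than being forced into either class, and they enter neither network.

Coupled taxa are additionally annotated by (a) an OLS regression of relative
abundance on net_Nmin/AP (Bonferroni over the coupled taxa tested) — the
ratio reflects the joint N-P process more directly than TN/TP — and (b) a
one-sided Mann-Whitney test for enrichment in coupled over decoupled sites,
BH-adjusted across taxa. The enrichment test is a deliberate choice: the
underlying comparison ("more abundant in coupled sites") is distributional,
group sizes are small and abundances are non-normal, so a rank test with FDR
control is the defensible default.

## Signed co-occurrence networks

Candidates for the coupled (resp. decoupled) network are the coupled_±
(resp. decoupled_N/_P) taxa, pooled across marker groups at one rank, that
are major (mean > 0.1%) and occur in strictly more than half of the sites.
All pairwise Pearson correlations among candidates are screened; after
**Benjamini-Hochberg** adjustment over every computable pair, an edge
requires |r| > 0.6 **and** adjusted p < 0.05 ("significant" is read on the
adjusted p because correction precedes the significance statement). Edges
carry the correlation as weight and its sign; isolated candidates remain
nodes — sparse soil networks routinely report more nodes than a
connected graph could justify, and connectance only reconciles with the
printed node/edge counts when isolated nodes are kept.

Metrics: connectance = edges / C(n, 2) (full precision plus a 2-decimal
display value); positive:negative edge ratio (infinite, serialized "Inf",
when there is no negative edge); edge-type composition over the
bacteria/fungi/phoD node classes (B-B, B-F, B-P, F-F, F-P, P-P) and the
fraction of edges touching a bacterial node.

**Keystones.** On the unsigned, unweighted skeleton: degree; *harmonic*
closeness normalized by (n−1) — chosen because these networks are sparse and
usually disconnected, where classic closeness is undefined across
components; betweenness normalized by (n−1)(n−2)/2. Each metric is
standardized across the network's nodes with the sample (n−1) standard
deviation (a zero-variance metric standardizes to all zeros), and the
combined score is z_degree + z_closeness − z_betweenness, flagged keystone
at ≥ 1. The combination as a *sum* with a negated betweenness term is this
package's reading of "high degree, high closeness, low betweenness combined
score with threshold ≥ 1"; the literature does not fix the formula, and the
choice is isolated in one function should a mean-based variant be wanted.

## Synthetic community generator

The generator emulates the study design so every stage is testable without
sequencing data: 35 sites, 10 of them drawn strictly above both site
thresholds (coupled-site TN/TP ~ U(3.4, 6.0), mean 4.70, matching the field
mean of 4.7; net_Nmin/AP ~ U(0.18, 0.40)), the rest failing at least one
threshold through three decoupling modes (slow N, slow P mineralization, or
both). The seven variables are log-normal around latent N- and P-speed
factors with heavier within-N loadings, so N-cycling variables cluster more
tightly with each other than across families, as observed in this kind of
survey data.

Taxa are organized into synthetic genera (3-5 features each) nested in
phyla; planted labels live at the genus level (fractions: 20% coupled, 15%
decoupled_N, 15% decoupled_P, the rest signal-free). Latent abundances are
log-normal (σ = 0.4) around linear combinations of standardized anchor
variables; the loading compensates analytically for log-normal attenuation
so the realized genus-level Pearson correlation approximates `target_r`
(default 0.85). Coupled taxa anchor on the most positively correlated
cross-family variable pair — a taxon can only correlate at r with both
members of a pair whose own correlation is ≥ 2r² − 1, so the dual-family
target is planted where it is attainable. Decoupled taxa anchor on the
family member with the least cross-family leakage. Coupled taxa are
additionally boosted ×3 (positive) or ÷3 (negative) in coupled sites,
mirroring the observed enrichment of coupled taxa there. Counts are
multinomial draws of each site's depth (uniform in 30,000-65,000) over the
latent proportions, so site sums equal depths exactly. Each marker group
consumes an independent sub-stream of the seed.

What the generator does **not** emulate: phylogenetic correlation between
related taxa, spatial autocorrelation among sites, realistic taxon-abundance
distributions, or the compositional bias structure of real libraries beyond
the closure that multinomial allocation itself induces. Passing recovery
tests therefore demonstrates the statistical machinery is correct and
calibrated under the planted model, not that real communities would be
classified with the same accuracy.

## Numerical choices and degenerate inputs

* Pearson r is computed vectorized (standardized cross-products); p-values
  via the exact t-transform with n−2 degrees of freedom; |r| = 1 maps to
  p = 0. Tests cross-check per-pair values against `scipy.stats.pearsonr`
  and a textbook double-loop implementation.
* Strictness conventions: floor filter removes strictly-below; major-taxon,
  occupancy, site-threshold and edge rules are all strict inequalities.
* Empty candidate sets produce a warning and an empty network report, not an
  error; metrics need ≥ 2 nodes, keystone scoring ≥ 3.
* Reports serialize as sorted-key JSON; infinities as "Inf", undefined
  fractions as "NA". End-to-end determinism (byte-identical reports under a
  fixed seed) is part of the test suite.

## Problem sizes

The default synthetic study is 35 sites with 120/80/48 features per marker
group (roughly 30/20/12 genera), 100 rarefaction repetitions; recovery and
power rates in the acceptance script aggregate 50 generator seeds. These
sizes give stable rates (binomial SE below 1 percentage point on recovery)
while keeping a full run in tens of seconds.

## Known limitations

* Pearson on relative abundances ignores compositional coupling (the
  closure effect); compositional-aware estimators (SparCC and relatives)
  are deliberately out of scope since the method under study uses plain
  Pearson. The generator's signal-free taxa pick up a small closure-induced
  negative bias, visible as the few-percent false-coupling rate.
* The Bonferroni family definition (global vs per-taxon) changes label
  counts on real data; both modes are exposed.
* Phylum-level labels aggregate heterogeneous genera and can be diluted or
  sign-mixed relative to their members; this mirrors the phylum/genus
  divergence seen in field data and is not corrected for.
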