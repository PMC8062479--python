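# Methods

## Model

The simulator is a MacArthur-type consumer resource model (CRM) with
cross-feeding.  Each of `S` species carries a stoichiometric uptake
matrix row `C_i·`; uptake of resource `a` proceeds at
`C_ia R_a / (k + R_a)` (Monod kinetics).  Consumed flux is weighted by
the resource's energy content `w_a`; a fraction `l_a` of it leaks back
into the medium as secreted byproducts, distributed over byproduct pools
by the per-species conversion matrix `D_abi`, and the remaining
`1 − l_a` is converted to biomass through the growth conversion factor
`g_i`, less a maintenance requirement `m_i`:

    dN_i/dt = g_i N_i [ Σ_a w_a (1 − l_a) C_ia R_a/(k + R_a) − m_i ]
    dR_a/dt = − Σ_i C_ia N_i R_a/(k + R_a)
              + Σ_{i,b} D_abi (w_b/w_a) l_b C_ib N_i R_b/(k + R_b)

The consumption term carries a negative sign — resources are depleted by
uptake; the inflow term adds only to byproduct pools.  Byproducts are
terminal: they can be consumed (the byproduct columns of `C` are
populated by the same Bernoulli(θ) rule as the primaries) but are never
converted onward, so the leaked fraction of byproduct consumption is
lost.  `D` columns are normalized to sum to 1 over byproducts (or 0 when
no conversion is drawn), conserving mass at the conversion step.

Serial passaging emulates batch culture: `n_passages` batches of
`passage_interval` hours; between batches species are diluted by
`dilution_factor`, primary resources are reset to the medium's
concentrations, and byproduct pools are emptied.

### Assumptions

* Well-mixed batches, deterministic dynamics (no demographic noise).
* All species share one Monod constant `k`; with `k = 1e4` and resource
  pools of order 1, kinetics are far from saturation (near-linear in
  `R`), so uptake competition is proportional to `C_ia N_i`.
* Uniform energy content `w` for primaries and byproducts, hence
  `w_b/w_a = 1` in the conversion term.
* Maintenance enters multiplicatively through growth (`g_i N_i m_i`), so
  starving populations decay exponentially.

## Parameters

| parameter | default | units | notes |
| --- | --- | --- | --- |
| `g` | 1 | (energy flux)⁻¹ h⁻¹ | growth conversion |
| `w` | 1e8 | CFU/mL per (g/mL) | energy content; sets the biomass scale |
| `m` | 0.1 | h⁻¹ (energy-rate units) | maintenance; see calibration below |
| `l` | 0.8 | — | leakage fraction of consumed flux |
| `k` | 1e4 | g/mL | Monod half-velocity |
| `dt` | 0.01 | h | Euler step |
| `passage_interval` | 48 | h | batch duration |
| `n_passages` | 6 | — | 288 h total |
| `dilution_factor` | 1/30 | — | 10 µl into 290 µl fresh medium |
| `N0` | 6e6 | CFU/mL | initial abundance per species (≈ OD 0.05) |
| `R_total0` | 1.5 | g/mL | total carbon per medium (≈ 50 mM C) |
| `uptake_scale` | 1e-2 | per (g/mL) h⁻¹ | magnitude of nonzero `C` entries |
| `theta` | regime-dependent | — | per-species usable-resource fraction |
| `transition_probability` | 0.25 | — | chance a byproduct is produced from a given primary |
| survival threshold | 1e-3 | relative abundance | survivor-set / richness cutoff |

### Calibration of `m` and `uptake_scale`

Neither the maintenance rate nor the absolute magnitude of uptake rates
is directly measurable in this setting, so both were fixed once against
the model's own required behaviours:

* **`m = 0.1`.** Per-passage endpoint biomass must reach a steady state
  under the 48 h / 1:30 dilution regime.  Scanning `m` shows stable
  passage-to-passage endpoints for `m ≤ 0.1` and oscillatory
  boom-and-bust endpoints for `m ≥ 0.2`; `m = 0.1` is the largest steady
  value, and large enough that species without usable resources wash out
  within two passages.
* **`uptake_scale = 1e-2`.** Two constraints: a single generalist must
  consume a 1.5-unit single resource well within one 48 h batch, and —
  more stringently — consumption must finish early in the batch at
  *every* complexity level.  At `1e-3` the slowest resources in a
  32-source medium are still being consumed while earlier-grown biomass
  is already paying maintenance, which injects a spurious
  complexity-dependent trend into yields (the θ = 1 yield-epistasis
  distribution acquires |mean| ≈ 0.27 sd).  At `1e-2` consumption
  completes within the first hours at all levels and the θ = 1 baseline
  is additive (|mean| ≈ 0.08–0.10 sd).  Niche overlap ρ is invariant to
  this scale.

### Yield definition

Growth yield is the *peak* total biomass within the final batch minus
the biomass that batch started from, floored at zero.  Using the 48 h
endpoint instead would subtract up to ~40 h of maintenance decay after
resource exhaustion, which (a) does not correspond to what an endpoint
OD read of a non-lysing culture measures and (b) systematically
penalizes media whose resources are exhausted earliest, biasing the
yield-epistasis null.

### Survival threshold

Simulated richness counts species whose endpoint *relative* abundance is
≥ 1e-3, emulating the practical detection floor of amplicon sequencing
at ~10⁴ reads.  Because washout of non-growers is exponential under
dilution, the counted survivor set is insensitive to this cutoff over
several orders of magnitude; the absolute value of mean richness at high
complexity is, however, sensitive to the `m`/threshold pair, and the
defaults above are reported as the package's chosen calibration.

## Environment schemes

Both designs keep total carbon fixed (default 1.5, split equally among a
medium's members) so that environmental complexity varies at constant
energy supply.

* **Hierarchical** (on `2^k` sources): singletons; then rank-extreme
  pairs (lowest `rank_score` with highest, second-lowest with
  second-highest — ties broken by resource id); then successive merges
  of adjacent composites in listing order up to the full panel.  On 32
  sources: 63 media, 31 composite→(A, B) links.
* **Full-subset** (on `n ≤ 12` sources): all `2^n − 1` nonempty subsets.
  Each subset of size ≥ 2 is linked to a canonical bipartition — the
  subset minus its highest-ranked member, paired with that member — or,
  with `all_bipartitions=True`, to every unordered disjoint bipartition.
  The canonical choice makes the epistasis edge set deterministic; the
  exhaustive mode exists because for subset designs there is no unique
  defensible bipartition.

## Epistasis, outcome types, statistics

`E_Y` uses an additive expectation (mean of constituents — equal total
carbon implies a combined medium should yield the average of its halves,
since each constituent's carbon is present at half weight).  `E_S` and
`E_H` use `max(A, B)` as a lower-bound expectation: a combined medium
should support at least the more diverse constituent community.
Measurements flagged as no-growth contribute survivor set ∅ (S = 0,
H = 0) and yield 0 to these scores (a `no_growth_yield="measured"`
option keeps the measured OD instead).

Outcome classification uses the precedence I > II > III > IV, so a novel
surviving species dominates the label even when the set also matches the
union or one side; on a richness tie either constituent's survivor set
qualifies for Type III.  The rules are exhaustive and mutually exclusive
(property-tested against a brute-force rule table over all 4096 triples
of a 4-taxon universe).

Distribution summaries report mean, sd, a one-sided one-sample t-test
against 0, and a one-sided paired t-test against a baseline distribution
(falling back, flagged, to an independent-samples test when lengths
differ).  The test direction is an explicit argument, recorded in the
result.  Identical paired distributions report p = 0.5 (no evidence in
either direction) rather than the NaN a zero-variance t-statistic would
give.

## Preprocessing pipeline

Plate tables are blank-corrected (and evaporation-corrected when
controls are present), screened per environment with the modified MAD
Z-score `M_i = 0.6745 (x_i − median) / MAD` at cutoff 3.5 (MAD = 0
removes nothing), and growth is called by a one-tailed two-sample t-test
against negative controls at α = 0.05 *and* a mean corrected OD of at
least 0.05.

A property of the MAD rule worth knowing: on triplicates with iid
Gaussian noise it is trigger-happy — it flags some replicate in ~29% of
clean triplicates (whenever the larger of the two replicate gaps exceeds
5.19× the smaller) and catches a 10-sd-shifted replicate only ~80% of
the time (whenever the two clean replicates lie within ~1.9 noise-sd of
each other).  With real plate-reader noise, which is less heavy-tailed
between replicates than iid Gaussian, removal rates are much lower.  The
filter is implemented exactly as defined; these rates are intrinsic to
MAD at n = 3, not tunables.

Environment clustering computes Spearman correlations between
composition vectors, then UPGMA (average linkage) on Euclidean distances
between correlation rows; constant composition vectors are dropped with
a warning, ids are sorted for deterministic leaf order, and the
dendrogram exports as Newick with ultrametric branch lengths.

Biomass conversion uses 8e8 CFU/mL per OD600 unit (OD 0.3 ≈ 2.4e8
CFU/mL), linear in both directions.

## Synthetic data

The generator produces the exact table dialects the pipeline consumes:

* plate tables: per environment, 3 replicates = truth + Gaussian noise
  (default sd 0.01 OD, typical plate-reader repeatability; readings
  truncated so corrected ODs are nonnegative) + optional planted
  epistasis offsets on composites and planted single-replicate outliers;
  blank and negative-control wells included;
* monoculture profiles: species × resource yield matrices with usable
  fraction θ_i and yields uniform on [0.1, 0.6] OD;
* abundance tables: multinomial read sampling (default depth 10⁴) of
  normalized endpoint compositions, 3 replicates per environment.

`additive_truths` propagates leaf yields up a combination tree so every
true epistasis value is exactly zero — the natural ground truth for
recovery tests.

What the generator does *not* emulate: replicate-correlated (plate- or
edge-) effects, OD nonlinearity at high biomass, compositional bias and
chimeras in amplicon data, or taxon misassignment.  Passing recovery
tests therefore demonstrate correctness of the analysis chain under
idealized noise, not robustness to real-world measurement structure.

## Numerics

Fixed-step explicit Euler at `dt = 0.01 h`, with any negative component
clamped to zero after each step; non-finite states abort with the step
index.  Halving `dt` changes endpoint biomass by < 0.1% on default
scenarios (asserted in the test suite).  The multi-environment engine
vectorizes the same update across all media of a scheme (requires the
shared scalar `k`) and matches the single-environment integrator to
1e-10 relative; a closed-form energy balance (`ΔN = g w (1 − l) ΔR` for
one species, one resource, `m = 0`) holds to 1e-6.

Ensembles draw a fresh θ vector (in `sampled_range` mode), `C`, and `D`
per replicate and byproduct count from a single spawned seed sequence;
identical seeds give bit-identical results.  Scaling summaries average
within each byproduct count first, then across counts, so each
cross-feeding regime contributes equally.

## Known limitations

* The absolute biomass scale is approximate: with `l = 0.8` and one
  conversion level, at most ~36% of supplied resource energy becomes
  biomass, so simulated ODs sit near the experimental growth-call
  threshold when converted at 8e8 CFU/mL per OD.  Relative quantities
  (epistasis, richness, overlap) are unaffected.
* With the frozen defaults, uniform-θ (θ = 0.5) 13-species ensembles
  peak at ~8 mean coexisting species at the 32-source level.  The
  increasing-richness shape, its flattening under generalist–specialist
  θ, and the negative shift of the diversity-epistasis distributions are
  robust; the peak height itself is sensitive to the `m`/threshold
  calibration and should be read as order-of-magnitude.
* Byproduct identities are abstract pools, not metabolites; no
  byproduct-to-byproduct conversion chains.
* The full-subset scheme's epistasis edges depend on the chosen
  bipartition convention (canonical vs exhaustive).
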