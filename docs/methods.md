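# Methods

This note documents the model that `silvatau` implements, the choices made
where the design was open, and what the synthetic experiments do and do not
show about real forests.

## Scope and intent

The package is a deliberately reduced, desk-scale analogue of a continental
forest-management experiment run with a full dynamic global vegetation model.
The quantities under test are *accounting identities and contrasts*: how
harvest partitioning, rotation management, disturbance and soil cascading
shape carbon turnover times (τ), and in which direction management and
climate change move them.  Tree physiology is intentionally simple; absolute
τ values from the synthetic grid are not comparable to continental estimates
driven by observed climate and forest structure.

## Vegetation model

A grid cell carries one analysed stand of 25 patches; patches hold cohorts
with stem (stem + branches + coarse roots), leaf and fine-root carbon, an age
and a stem density.  The annual step is, in order: planting, production,
mortality, fire, management, disturbance, soil, recording.  Stand values are
per-m² means over the analysed patches.

**Production.**  Patch light capture is `1 − exp(−k·C_leaf,patch)` with
`k = 3.5` per kgC leaf, shared among cohorts in proportion to leaf carbon, so
understorey cohorts are suppressed.  Cohort assimilation is
`GPP = pmax · fT · fCO2 · (rad/0.75) · light`, with a Gaussian temperature
response (optimum 10–20 °C by PFT, width 12 °C) and a logarithmic CO₂
multiplier `1 + β ln(CO2/400)`.  β defaults to 0.15 — a weak fertilisation
response, so that the warming response of turnover is respiration-led (higher
autotrophic and heterotrophic outflows) rather than stock-led; this is the
mechanism the experiment is designed to express.  Maintenance respiration is
Q10 = 2 on leaf (0.18 yr⁻¹), fine root (0.22 yr⁻¹) and stem (0.12 yr⁻¹;
0.16 yr⁻¹ for the high-respiration broadleaved evergreens); growth
respiration is 25 % of the surplus.  Net production first replaces leaf and
fine-root turnover; the remainder is allocated 0.30/0.10/0.60 to
leaf/root/stem, except that leaf growth stops at a PFT-specific canopy cap
(0.5–0.7 kgC m⁻²) and root growth above a 1:1 root:leaf ratio, with withheld
shares going to the stem.  This yields a stable, monotone fixed point under
constant forcing (the basis of the steady-state tests): stem respiration
rises with stock until surplus production vanishes.

**Establishment.**  Planting creates a sapling cohort (0.25 stems m⁻²,
5 gC m⁻² total).  First-year seedling production is counted inside GPP in the
planting year, so the ledger identity ΔC_eco = GPP − F_turn,eco holds exactly
every simulated year; the term is three orders of magnitude below canopy GPP.

**Mortality.**  Three channels: a background annual probability per PFT
(0.5–1.2 % yr⁻¹), an ageing ramp `0.25·(age/longevity)^6`, and a
growth-efficiency stress term that adds up to 30 % yr⁻¹ as NPP per unit leaf
carbon falls below 0.08 yr⁻¹.  Stem deaths are binomial draws on the integer
stem count (patch area 1000 m²).  A cohort whose climate tracker (exponential
moving average of annual temperature ± the cell's seasonal amplitude) leaves
its bioclimatic envelope dies whole; envelope constants are coarse
coldest-month and warmest-month limits per PFT chosen so that broadleaved
evergreens fail in cold-winter zones and needle-leaved deciduous trees only
persist in cold ones.

**Disturbance.**  Each patch is destroyed independently with annual
probability 1/interval (default interval 400 yr, applied in managed and
unmanaged stands alike).  Destroyed live carbon is routed to litter and
booked as the stem disturbance flux; regeneration follows the scenario rule
the next year.  Disturbance draws come from a dedicated per-cell stream so
all scenarios on a cell share one destruction sequence (a paired design).

**Fire.**  A parametric stand-in: unmanaged patches burn a fraction
`base (1.5 %) × dryness` of their area each year, with dryness a clipped
inverse of annual precipitation.  Combustion completeness is 0.7 for leaves,
0.2 for stems, and 0.3–0.7 for surface litter pools; half the remaining
burned-area stems die to litter.  Managed stands never burn.  Only live-stem
combustion enters the stem turnover flux; fire-killed-but-uncombusted stem
carbon reaches litter without passing through any stem outflow term — the
alternative attribution (counting it as fire mortality) would shorten
unmanaged stem τ by under one percent at the default rates.

**Height and the forest filter.**  Height follows a power-law allometry of
mean stem mass per tree, `h = 2.0 m^0.4` (m in kgC); cells whose
scenario-average, density-weighted stand height over the τ window is below
5 m are dropped, and comparisons use the intersection of retained cells
across scenarios.  A scenario retaining less than half the baseline's cells
is excluded from dominance-stratified comparisons as non-comparable in
extent.

## Management

Scenarios differ only in what is replanted after a death: `base` the
pre-death species, `toNE`/`toBD`/`toBE` a single PFT, `unmanaged` nothing
(natural regeneration of a locally viable PFT in emptied patches).  Managed
options clear-cut all patches in the same years — the management start and
every rotation (default 80 yr) thereafter; clear-cut patches are replanted
the same year, all other deaths after a one-year lag.  Between cuts, a patch
is thinned when its density exceeds the Reineke maximum
`N_max = k (D/25 cm)^−1.605` (k = 1050 stems ha⁻¹ for conifers, 700 for
broadleaves, so broadleaved stands thin earlier), removing stems
proportionally down to 0.9 N_max.  All felled biomass — clear-cut or thinning
— passes through one harvest pathway: 66 % of wood and 30 % of leaf carbon
removed, residues (including all fine roots) to litter, removed leaf plus
67 % of removed wood oxidised the same year, the rest to a product pool
oxidising at 4 % yr⁻¹ (oxidation applied before the year's input; the
alternative ordering differs in the fourth decimal at annual stepping).
The product pool sits outside the ecosystem: the export itself, not the later
oxidation, is the ecosystem outflow.

**Initialisation.**  History is emulated by clear-cut waves every 10 years
over the 140 years before the management start, apportioning the stand's
patches (largest-remainder) to a target 10-yr age histogram — default uniform
over 0–140 yr with a 4 % older-than-140 pristine tail.  Pristine patches are
never converted and are excluded from the analysed patch set (the analysis
covers the managed fraction; the `unmanaged` *option* is the conversion of
the analysed patches themselves at the start year).  Before the start, every
option replants the pre-death species, so all scenarios share one
initialisation history.

## Soil

Ten pools (surface CWD, FWD, structural, metabolic, humus; soil structural,
metabolic; active, slow, passive) with intrinsic rates spanning 5 yr⁻¹
(metabolic) to 4.5 × 10⁻⁴ yr⁻¹ (passive) and an explicit transfer matrix
(surface litter → humus → active; soil litter → active/slow; active ↔ slow →
passive), so alternative cascade readings are config edits.  Decay scales
with a Q10 = 2 temperature factor (capped at 3.5) and a saturating moisture
factor `P/(P+400 mm)`; DOC leaches from active-pool decay at coefficient 0.01
times the moisture factor.  Dead stems split 0.7/0.3 into coarse/fine woody
debris; leaf and fine-root litter split metabolic vs structural by PFT lignin
fractions.  The year is integrated in 24 sub-steps with outflow booked as
rate × stock, which makes the step exactly mass-conserving and gives an
isolated pool at equilibrium a turnover time of exactly `1/(k·fT·g)` — the
closed-form anchor used in testing.  An analytic equilibrium solver
(`(I − Tᵀ) o = inputs`) both serves as an independent oracle and accelerates
spin-up: runs reset the soil state to the equilibrium of the trailing 30-yr
mean litter input 40 years before the end of spin-up (flagged in the ledger;
never inside an analysis window).  The slow and passive pools may remain
somewhat below their true equilibrium at the default 300-yr desk spin-up; a
1200-yr spin-up is one config field away.

## Forcing

Annual series only — the τ arithmetic is annual, and daily weather would add
nothing the reduced model can use.  Five grouped Köppen-Geiger classes are
retained (arid; cold with cold/warm summer; temperate with/without dry
summer; tundra is recognised but never assigned).  Each zone has a prototype
climatology (mean temperature, seasonal half-amplitude, annual precipitation,
summer precipitation share); cells get jittered copies (σ = 0.5 °C, 8 %
precipitation).  Fixed mode draws a 20-yr anomaly block per cell (σ = 0.6 °C,
12 % precipitation, 0.04 radiation index), centres it to zero mean, and
recycles it verbatim — block means are identical by construction — with CO₂
constant at 400 ppm.  Warming mode uses independent anomalies plus a linear
+0.04 °C yr⁻¹ trend and a 400→850 ppm CO₂ ramp over 90 years, both starting
at the management start (a high-warming trajectory; the pre-start historical
trend is omitted as negligible for a first-rotation τ window).  N deposition
is carried as a constant forcing field (0.8 gN m⁻² yr⁻¹) but the reduced
model has no nitrogen cycle.  Zone assignment from a climate summary uses
simplified Köppen thresholds (arid rule with seasonality-adjusted threshold,
−3 °C coldest-month boundary for cold climates, ≥4 months above 10 °C for
warm summers, Psummer < Pwinter/3 for dry summers).

## τ estimation

τ is the ratio of window means (stock over outflow), over the last 30 years
of the third rotation cycle in fixed mode and of the first cycle in warming
mode — half-open intervals, so the next clear-cut (falling exactly at the
window end) is excluded.  Stem-level harvest outflow is the *total felled*
stem carbon including the residue left as litter (a stem-pool exit), whereas
the ecosystem outflow counts only the exported shares.  Zero outflow yields a
missing value, never infinity.  Before zone averaging, values are trimmed to
the central 99 % quantile band using order-statistic band edges (small groups
are never over-trimmed); coverage is config, so the [1 %, 99 %] reading is
one flag away.  Zone statistics are means with standard errors across
retained cells (not across years); longest-τ ties break by the documented
scenario order base < toNE < toBD < toBE < unmanaged and are flagged.

## Reproducibility and problem sizes

Every stochastic component derives from one integer seed through named
SeedSequence spawns: grid, forcing, wave apportionment, one general stream
per (mode, scenario, cell) and one disturbance stream per (mode, cell).  Runs
are byte-reproducible from (config, seed).  Default desk-scale sizes — 20
cells, 25 patches, 300-yr spin-up, 140-yr initialisation, 240-yr (fixed) or
90-yr (warming) management period — run a full five-scenario, two-mode
experiment in about a minute on one core; the defaults are the package's
standing experiment conditions, not tuning knobs.

## Known limitations

* No nitrogen cycle, water balance or daily phenology; the CO₂ and
  temperature responses are single-multiplier stand-ins.
* Disturbance frequency is independent of species composition and climate,
  and fire is a parametric fraction rather than a process model — both noted
  drivers of turnover divergence in real forests.
* Under warming, stem τ in managed stands does not lengthen as consistently
  as a stock-led (strong CO₂ fertilisation) regime would produce; with the
  respiration-led default the ecosystem and soil responses dominate.
* The synthetic grid has no spatial structure (no neighbour effects, no
  maps); zone contrasts reflect prototype climatologies plus jitter, so
  passing tests demonstrate the machinery and directions of response, not
  continental magnitudes.
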