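# Methods

## Mass-balance growth-rate estimation

The package models a semi-continuous, completely mixed fermenter: every
`exchange_interval_d` days, `exchange_volume_ml` of mixed liquor is
withdrawn and replaced by the same volume of feed sludge. Complete mixing
means the discarded fraction of volume equals the discarded fraction of
solids, so the solids retention time is purely geometric,
`SRT = Vc * exchange_interval / exchange_volume`.

Cell counts are approximated by biomass via the volatile suspended solids
(VSS) concentration: taxon `x`'s standing stock is `N_x = Vc*Cc*p_xc` and
its feed influx is `Q*Cf*p_xf`, with `p` the 16S relative abundance in the
reactor (`c`) and feed (`f`) samples. Setting `dN_x/dt = 0` in the balance
`dN_x/dt = influx − discard + mu_x*N_x`, and using well-mixed discard
(`Cd = Cc`, `p_xd = p_xc`, hence `discard/N_x = 1/SRT`), gives

    mu_x = 1/SRT − (Qf*Cf*p_xf) / (Vc*Cc*p_xc)    [1/d]

Internally everything is carried in (mg, mL, d); the identical `C*V`/`C*Q`
unit products cancel, so configs may state VSS in g/L and volumes in mL
directly. Output tables round `mu` to 4 significant figures.

Assumptions this estimator inherits, and how the package treats them:

- **Steady state.** The estimator is only meaningful once the community has
  stopped changing. `assess_steady_state` flags OTUs whose coefficient of
  variation of `p` over the final ≥3 sampling days exceeds a threshold
  (default 0.3, roughly "stays within ±30% of its mean"); flags are carried
  as annotations, never used to drop data silently.
- **Washout.** `p_reactor = 0` with `p_feed > 0` means the taxon could not
  be retained at this SRT. It gets status `washed_out` and an undefined
  `mu`: any pseudocount would manufacture an arbitrarily negative rate from
  the detection limit. No pseudocounts are used anywhere by default.
- **16S copy number** is not corrected; relative abundances are taken as
  biomass proxies as-is. This is a known limitation of abundance-based
  mass balances, stated here rather than patched.
- **Which VSS is `Cc`** is a user decision (`ReactorConfig.with_cc`);
  typically the final-day measurement, matching the sampling day of the
  abundances.

## Dominant-OTU filtering

Two dominance criteria are exposed independently: fraction > `any_sample`
threshold (default 2%) in at least one sample, and pooled fraction >
`total` threshold (default 0.1%). Either or both may be enabled; the two
packaged experiment presets use any-sample-only and total-only respectively.
Because a `RelAbundanceTable` no longer carries read depths, "pooled"
abundance is the across-sample mean of the fractions (equal-weight pooling
of samples); with equal sequencing depth this equals pooled-read abundance.
Filtering deliberately does **not** renormalize the retained fractions: the
estimator needs whole-community fractions, and renormalizing after
filtering would inflate every `p` and bias `mu` upward. Replicate averaging
operates on fractions, not counts, so bottles with unequal depth weigh
equally; selection-before-averaging is the default order and the CLI's
filter options apply before the growth computation.

## Guild classification

Known syntrophs and methanogens are recognized by case-insensitive
substring match of curated keywords against the full lineage string, so
both family-level (`Syntrophaceae`) and genus-level (`Smithella`) keywords
work on SILVA-style lineages. Precedence is syntroph > methanogen > sign
rule. The sign rule bins `mu >= 0` as fermenter and `mu < 0` as
WAS-associated; exact zero is a measure-zero boundary and must not create a
fifth bin, and a maintained population is by definition not being
decomposed. Archaea matching no methanogen keyword fall through to the sign
rule with a warning, since no biological rule exists for non-methanogen
archaea in this system. The keyword file ships as editable plain text
(`src/egmb/data/guild_rules.txt`); because matching is by substring at any
rank, coarse keywords can over-match (e.g. `Syntrophobacter` fires on the
order name `Syntrophobacterales`), which is accepted — the guild is still
correct — and `rule_fired` records exactly which keyword matched.

## Performance metrics

Solid removal is `(VSSin − VSSout)/VSSin`; negative values (effluent above
feed) are reported with a warning, not clipped. VFA and alcohol
concentrations are converted to COD equivalents with theoretical-oxygen-
demand factors computed from full-oxidation stoichiometry,
`32*(x + y/4 − z/2)/MW` for CxHyOz, using nominal integer atomic masses
(C=12, H=1, O=16) — the convention under which acetate's factor is exactly
64/60. A passthrough flag accepts tables already expressed in mg COD/L.
CH₄ yield is cumulative mmol CH₄ over total g VS fed, with the denominator
computable from the feeding schedule as Σ(event volume × Cf).

## Synthetic communities

The simulator's state variable is per-taxon biomass [mg], standing in for
cell count exactly as VSS does in the estimator. Event ordering is fixed as
**grow → discard → feed**: between events biomass multiplies by
`exp(mu_true*tau)`; the discard scales all taxa by `(Vc−v)/Vc`; the feed
adds `v*Cf*feed_profile[x]` mg. The community sample is the pre-discard
state of the final event — the withdrawn aliquot is the sample. Feed-borne
taxa relax to the discrete fixed point `N* = f/(1 − exp(mu*tau)(Vc−v)/Vc)`
(per-event feed mass `f`); a feed-borne taxon with
`exp(mu*tau)(Vc−v)/Vc >= 1` has no bounded steady state and is rejected by
name. A `continuous_limit` mode integrates `dN/dt = mu*N − N/SRT + F` by
fixed-step Euler; on its analytic steady state `N* = F/(D − mu)` the
estimator is algebraically exact, which the tests verify to 1e-9.

Measurement noise: sequencing is a multinomial draw at configurable read
depth (default 1e5) with probabilities proportional to biomass — no
overdispersion, a documented simplification relative to real amplicon data;
VSS measurements get multiplicative lognormal noise (default CV 0.05). What
the simulator does **not** emulate: 16S copy-number variation, primer and
extraction bias, compositional overdispersion, chimeras, and any substrate/
product chemistry (performance fixtures come from declared schedules, not a
metabolic model). Passing recovery tests therefore demonstrate estimator
correctness under the model's own noise structure, not robustness to every
bias of real amplicon surveys.

`default_community` builds a 30-taxon community (any `n_taxa >= 8`): ~60%
feed-borne WAS biomass with decay rates uniform in [−0.8, −0.02] d⁻¹
(bracketing slow-decaying resistant populations and rapidly decomposed
aerobes), ~10% feed-borne slow growers with `0 < mu < 0.5/SRT`, and the
remainder reactor residents — syntrophs, methanogens, fermenters — placed
at the washout equilibrium of the event map
(`mu = −ln((Vc−v)/Vc)/tau ≈ 1/SRT`), the rate the operating scheme itself
enforces on persisting residents. Feed fractions are Dirichlet(5)
distributed over feed-borne taxa; feed-borne taxa start at their analytic
steady state and residents at 30 mg, so runs begin near equilibrium.
Lineage strings are drawn from genera characteristic of each role so the
guild classifier is exercised end-to-end.

## Numerical and design choices

- **Discretization of recovery studies.** The estimator is exact only in
  the continuous limit; per event interval `tau` the leading bias for a
  rate `mu` is ≈ `|mu|*tau/2`. Recovery studies therefore use
  `recovery_interval = min(SRT/50, 0.1/|mu|_max)` — fine enough to resolve
  both the dilution process and the fastest kinetics (≤5% bias at the
  default resolution). The semi-continuous/continuous discrepancy is a
  tested property, not hidden.
- **Simulation-study sizes.** The packaged parameter-recovery study runs
  30-taxon communities at SRT ∈ {2.34375, 10, 37.5} d, read depth 1e5,
  20 seeds per SRT, run length 20·SRT; median relative error of recovered
  rates for `|mu_true| >= 0.01` d⁻¹ is required ≤10% (measured ~6–8%; the
  VSS noise floor dominates).
- **Dual SRT printouts.** The most aggressive experiment-II schedule
  (32 mL / 0.5 d / 150 mL) computes to 2.34375 d; summaries round it to
  2.3 d. Computation always uses the schedule arithmetic.
- **Tie-breaks and degenerate inputs.** All-zero sample columns are errors
  at normalization (not silently dropped); all-zero OTU series are
  stable-absent for the steady-state check; `mu = 0` classifies as
  fermenter; `Cc = 0` with a detected OTU is a configuration error.
- **Determinism.** All randomness flows through one `numpy` Generator
  seeded from `SimConfig.seed`; identical config ⇒ byte-identical fixture
  files (the BIOM writer embeds a timestamp and is not used by the
  pipeline commands).

## Known limitations

Relative-abundance mass balance cannot distinguish a taxon growing slowly
from one decaying slowly when both sit near `mu = 0`; rates of taxa near
the detection limit carry large multinomial error; and the estimator's
ceiling `1/SRT` means feed-absent taxa are uninformative about their true
growth rate beyond "fast enough to persist". Absolute-abundance methods
(qPCR, flow cytometry) or metagenomic coverage would relax the 16S
copy-number and compositionality caveats.
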