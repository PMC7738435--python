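# egmb — ecogenomics-based mass balance for semi-continuous fermenters

16S rRNA gene surveys of engineered ecosystems report *presence*, not
*activity*: a sludge fermenter fed with waste activated sludge (WAS)
receives a massive influx of exogenous organisms, many of which are dead or
being decomposed while still contributing DNA to the community profile.
`egmb` implements the ecogenomics-based mass balance: it combines relative
abundances of each OTU in the feed and in the reactor with the reactor's
operating parameters and biomass (VSS) concentrations to estimate each
population's **net growth rate**, separating organisms that actually grow in
the fermenter from feed-borne biomass that is merely washing through or being
eaten.

It is intended for researchers and process engineers analyzing
semi-continuous anaerobic fermenters or digesters who have an OTU table
(reactor and feed samples), the exchange schedule, and VSS measurements.

## The model

For a well-mixed reactor of working volume $V_c$ that discards and replaces
$v$ mL of mixed liquor every $\tau$ days, the volumetric exchange rate is
$Q = v/\tau$ and the solids retention time is

$$\mathrm{SRT} = V_c / Q = V_c\,\tau / v .$$

The standing stock of taxon $x$ is approximated as $N_x = V_c\,C_c\,p_{x,c}$,
where $C_c$ is the reactor VSS concentration and $p_{x,c}$ its 16S relative
abundance; the feed contributes at rate $Q\,C_f\,p_{x,f}$. The mass balance
$\mathrm{d}N_x/\mathrm{d}t = \text{in} - \text{out} + \mu_x N_x$ at steady
state yields the estimator

$$\mu_x = \frac{1}{\mathrm{SRT}} - \frac{Q\,C_f\,p_{x,f}}{V_c\,C_c\,p_{x,c}}
\quad [\mathrm{d}^{-1}],$$

bounded above by the dilution rate $1/\mathrm{SRT}$, with equality exactly
when the taxon is absent from the feed. Negative $\mu_x$ marks feed-borne
(WAS-associated) biomass being decomposed; positive $\mu_x$ marks organisms
growing in the reactor. OTUs detected in the feed but not in the reactor are
reported as *washed out* rather than assigned a pseudocount-derived rate.
Each OTU is then binned into one of four guilds — known syntroph, known
methanogen, fermenter, WAS-associated — by taxonomy-keyword matching
(syntrophs and methanogens) with the sign of $\mu_x$ deciding the rest.

A built-in simulator propagates per-taxon biomass through the same
grow → discard → feed event cycle with known true rates, multinomial
sequencing noise and lognormal VSS noise, so the whole pipeline is
verifiable against ground truth without external data.

## Worked example

Simulate a 10-taxon community under the 100-day-SRT schedule (150 mL, 3 mL
exchanged every 2 d), then estimate growth rates and assign guilds:

```sh
egmb simulate --preset toy --out demo --seed 0
egmb classify --otu-table demo/otu_table.tsv --reactor-config demo/reactor.yml \
    --out demo/guilds.tsv
```

`demo/guilds.tsv` (columns abridged):

```
otu_id  taxonomy                 p_reactor  p_feed   mu_per_day  status     guild           rule_fired
OTU1    ...Terrimonas            0.0047     0.11905  -0.4364     estimated  was_associated  sign:mu<0
OTU5    ...Saprospiraceae        0.0127     0.13315  -0.1748     estimated  was_associated  sign:mu<0
OTU7    ...Parabacteroides       0.44955    0.1604   0.003712    estimated  fermenter       sign:mu>=0
OTU9    ...Syntrophomonas        0.06185    0        0.01        estimated  syntroph        taxonomy:Syntrophomonas
```

Reading the numbers: the *Terrimonas*- and *Saprospiraceae*-related OTUs are
abundant in the feed but rare in the reactor — their negative rates
(−0.44, −0.17 d⁻¹) say they are sludge biomass being decomposed.
*Parabacteroides* grows (+0.0037 d⁻¹), i.e. it is an active fermenter, and
the feed-absent *Syntrophomonas* sits exactly at the dilution ceiling
1/SRT = 0.01 d⁻¹. The fixture's `truth.tsv` carries the generating rates for
comparison. `egmb report` condenses the same analysis to the top-eight most
abundant OTUs per guild; `egmb performance` computes solid removal
(VSS_in − VSS_out)/VSS_in, total volatile fatty acids in mg COD/L (factors
from full-oxidation stoichiometry, e.g. 64/60 for acetate), and CH₄ yield in
mmol per g volatile solids fed.

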