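# siactors

Actor networks and Bayesian belief networks for the uptake of sustainable
intensification (SI) measures in a peri-urban farming region.

## The problem

Peri-urban landscapes combine intensive agriculture with dense demands for
recreation, biodiversity and local food. Whether farmers adopt SI measures —
maintaining small landscape elements (hedgerows, tree lines), farm-level
efficiency measures, or direct sales — depends not only on farm structure
but on a web of actors: retail and purchasers, labels, consumers, farmer
networks and organizations, the province, and national/EU government. This
package models a Dutch case-study region of 284 dairy and 71 fruit farms and
asks *which groups of actors enable or block uptake*.

It is written for researchers in agro-environmental decision modelling who
want a fully synthetic, reproducible re-implementation of that analysis: the
underlying farm accounts, payment records and interview matrices are
confidential, so every input is emulated by generators whose structure
matches the published summary tables.

## What it computes

**Influence network.** Interview-derived actor-to-actor influence entries
(none/low/high/mandatory, coded 0/1/2/3) become a directed weighted graph per
topic. Per actor: weighted indegree (influence experienced), weighted
outdegree (influence exerted), and unnormalized betweenness centrality on
hop-count shortest paths.

**Belief networks.** One discrete Bayesian network per sector with 24 nodes:
actor attitude roots → advice per measure; Province and NL&EU → subsidies and
regulations; farm characteristics (intrinsic attitude, age, innovativeness,
successor, size, location) and advice → intention (Theory of Planned
Behavior) → uptake. Advice CPTs follow a rank-based elicitation: the
top-ranked actor's state sets a baseline `b`, lower-ranked actors add
`±δ·γ^(k−2)` (supportive/unsupportive at rank k), clamped to `[ε, 1−ε]`.
Intention CPTs are additive in log-odds; uptake is a two-probability link
`(π₁, π₀)` with `π₁ > π₀`. Free parameters are calibrated by staged monotone
1-D solves so the baseline marginals reproduce the published tables to well
under 0.01. Inference is exact (variable elimination, checked against full
joint enumeration).

**Scenarios.** Fourteen sensitivity runs force actor groups (all,
external/local, government/market, informal/formal) supportive or
unsupportive. Each run reports uptake per measure, percent change vs
baseline, and a synergy/trade-off class: `S+` (all three indicators up),
`S−` (all down), `T` (mixed). Per-farm supportive-minus-unsupportive
differences are mapped onto the synthetic farm coordinates (GeoJSON).

**Efficiency scoring.** The FoA2 adoption proxy: per-measure lower-decile
thresholds on a country-level pool of 12 bookkeeping measures, per-farm 0/1
adoption and counts, sector means.

## Worked example

```python
from siactors import assemble_si_network, calibrate, run_suite

result = calibrate("dairy")
print(f"max |deviation| from printed baselines: {result.max_abs_deviation:.4f}")

net = assemble_si_network("dairy", result.params)
suite = run_suite(net, "dairy")
cols = ["scenario", "class", "pct_change_FoA1_3", "pct_change_FoA2", "pct_change_FoA4"]
print(suite[cols].round(1).tail(4).to_string(index=False))
```

prints

```
max |deviation| from printed baselines: 0.0000
                    scenario   class  pct_change_FoA1_3  pct_change_FoA2  pct_change_FoA4
I supportive, F unsupportive       T              -28.8            -16.7             25.6
     I supportive, F neutral  S_plus                1.7              2.1             31.7
     All actors unsupportive S_minus              -31.9            -20.7            -30.9
       All actors supportive  S_plus               28.4             18.7             37.8
```

Reading: with every actor supportive, uptake of all three measures rises
(a synergy, `S_plus`); informal actors alone mainly move direct sales
(+31.7%); a fully unsupportive actor landscape depresses everything
(`S_minus`). The same pipeline is available from the shell:

```sh
siactors generate --out out/pop --seed 1
siactors calibrate --sector dairy --out out/dairy.json
siactors scenarios --model out/dairy.json --sector dairy --farms out/pop/farms.csv --out out/scen
siactors network --topic FoA4 --out out/net
```

## Layout

| module | contents |
| --- | --- |
| `siactors.population` | synthetic farm population, location classes, I/O |
| `siactors.jenks` | natural-breaks 1-D classification |
| `siactors.influence` | influence matrices, indicators, GraphML |
| `siactors.bbn` | discrete BBN engine: validation, variable elimination, enumeration oracle, JSON |
| `siactors.simodel` | SI network assembly, rank-based elicitation, calibration |
| `siactors.scenarios` | scenario suite, trade-off classes, spatial impact |
| `siactors.scoring` | efficiency-measure thresholds and adoption counts |
| `siactors.tables` | printed case-study constants |
| `siactors.cli` | `siactors` command group |

See `docs/methods.md` for the model description, parameter meanings and
limitations.
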