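# samtrace

Quantitative analysis of the SAM transmethylation pathway and adenosine
recycling in *Drosophila* hemocytes, driven by ¹³C stable-isotope tracing.

During parasitoid wasp infection, activated hemocytes ramp up the
S-adenosylmethionine (SAM) transmethylation pathway: methionine + ATP →
SAM → (methylation) → S-adenosylhomocysteine (SAH) → homocysteine +
adenosine. Every methylation event releases one adenosine, which the cell
either recycles back to ATP (adenosine kinase → adenylate kinase →
glycolysis) or exports through the equilibrative nucleoside transporter as
a systemic "send nutrients" signal that delays larval development. This
package implements, as a tested reusable pipeline, the computations such a
study needs:

* **`samtrace.pathway`** — a deterministic, moiety-resolved
  label-propagation simulator of the pathway (Met-¹³C₅ and Ado-¹³C₅
  tracers, 3% m+4 stock impurity, infection- and RNAi-dependent enzyme
  capacities, a nutrient-supply axis for the activity/nutrient-balance
  hypothesis), an instrument-facing peak-table emitter with seeded
  log-normal noise, and a pupation/survival cohort generator.
* **`samtrace.isotopologue`** — reference-sample normalization factors,
  isotopologue fractions *f*(m+k) = A(m+k)/ΣA, methylation index
  (SAM:SAH), the remethylation threshold test
  r = m+4/(m+4+m+5) vs the stock impurity, the adenosine→SAM recycling
  fraction, per-protein extracellular purine summaries, and the figure
  statistics (unpaired *t*, one-way ANOVA + Tukey).
* **`samtrace.expression`** — TPM (3′-end-seq mode by default), the
  15-TPM threshold summary, ΔΔCt fold changes against an RpL32 reference,
  and counting genes significant at both 9 and 18 hpi in a consumed DE
  table.
* **`samtrace.phenotypes`** — pupation curves, the t50 delay estimator
  (time to 50% of each arm's own plateau, interpolated), log-rank tests
  (via lifelines), survival-to-adult with melanized-egg exclusion, and
  lamellocyte summaries.
* **`samtrace.cli` / `samtrace.config`** — `samtrace simulate | analyze
  tracer|expression|phenotypes | run | fixtures`, with one global seed,
  YAML configs and a run manifest.

## Worked example

```python
from samtrace.pathway import build_scenario, simulate_tracer
from samtrace import isotopologue as iso

uninf = simulate_tracer(build_scenario(genotype="control", infected=False,
                                       tracer="Met-13C5"))
inf = simulate_tracer(build_scenario(genotype="control", infected=True,
                                     tracer="Met-13C5"))
print(round(uninf.labeled_fraction("Met"), 3),
      round(inf.labeled_fraction("Met"), 3))
# 0.727 0.854
print(round(inf.endpoint_amount("SAM") / uninf.endpoint_amount("SAM"), 2))
# 2.0
```

After a simulated 20-minute ex vivo incubation in 0.33 µM Met-¹³C₅ medium,
73% of the intracellular methionine pool is labeled in resting hemocytes
and 85% in activated ones — the uptake acceleration that marks immune
activation — while SAM levels double with infection. Under the adenosine
tracer the endpoint SAM m+5 : ATP m+5 fraction ratio is ≈0.13: about 13%
of labeled ATP is drawn into SAM synthesis, the signature of adenosine
recycling feeding the methylation cycle.

The same numbers fall out of the file-based interface:

```bash
samtrace run --seed 1 --out results/run1    # tables + JSON summaries + manifest
samtrace fixtures --seed 1 --out fixtures/  # small bundled datasets
```

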