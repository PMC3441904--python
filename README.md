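# smrfunnel

Funnel-plot control limits for the standardised mortality ratio (SMR) under
a Poisson model — and the *true* probability that an in-control provider is
flagged by them.

## The problem

Health-care providers are routinely compared on the SMR, the ratio of
observed to expected events (deaths, complications), with observed counts
O ~ Poisson(λ) where λ is the expected count from indirect standardisation.
Funnel plots display each provider's SMR against λ with a target line at
SMR = 1 and nested control limits — conventionally 95% "alarm" and 99.8%
"action" limits — and a provider falling outside a limit is investigated as
a potential outlier.

Three constructions of those limits are in common use:

- **Wald** confidence limits: λ ± z₁₋α/₂·√λ;
- **'exact'** confidence limits via the chi-square/Poisson link:
  lower = ½·χ²(α/2; 2λ), upper = ½·χ²(1−α/2; 2λ+2);
- **probability-based prediction limits** read off the Poisson CDF:
  the lower limit L is the smallest integer with P(X ≤ L) ≥ α/2 and the
  upper limit U the largest integer with P(X ≥ U) ≥ α/2 (the conservative
  tail rule; liberal and FUNNELCOMPAR-style asymmetric rules are also
  provided).

Because counts are discrete, no limit can achieve an outside-probability of
exactly α/2 — at λ = 10 the probability of observing more than 16 events is
0.027 and of more than 17 events is 0.014; there is nothing in between. The
actual flagging probability of an in-control provider therefore depends
strongly on the method and on λ, and can be far from the nominal value.
This package constructs the limits, computes the true outside-probabilities
directly from the Poisson CDF (an observation exactly on a limit counts as
inside), sweeps them over λ, summarises them by λ range, classifies real or
simulated provider tables, and renders funnel plots.

## Worked example

Limits for a provider with λ = 10 expected events, 95% level:

```bash
$ smrfunnel limits --lam 10 --method all --level 0.95
lam,method,level,lower,upper,smr_lower,smr_upper
10.0,wald,0.95,3.8020496769543843,16.197950323045617,0.38020496769543843,1.6197950323045618
10.0,exact,0.95,4.7953886961324335,18.39035604201778,0.4795388696132433,1.839035604201778
10.0,prediction,0.95,4.0,17.0,0.4,1.7
```

The prediction limits are the integers (4, 17): observing 18 or more events
(SMR ≥ 1.8) flags a provider high, with true probability
P(X > 17) = 0.014 ≤ 0.025; the Wald upper limit 16.2 flags already at 17
events (true probability 0.027, above nominal), while the exact upper limit
18.4 flags only at 19 (0.0072, far below nominal).

How each method's true upper-tail probability behaves for small units
(1 ≤ λ ≤ 50, 95% limits), from the coverage sweep:

```python
>>> import smrfunnel as sf
>>> tab = sf.coverage_table()   # full 60-cell summary, fine lambda grid
>>> tab[(tab.level == 0.95) & (tab.tail == "upper") & (tab["range"] == "1-50")]
range     method  level  tail  median    min    max
 1-50      exact   0.95 upper  0.0121 0.0003 0.0177
 1-50 prediction   0.95 upper  0.0201 0.0052 0.0250
 1-50       wald   0.95 upper  0.0301 0.0203 0.0840
```

Reading the medians: for small providers a nominal 2.5% upper tail is in
truth typically 3.0% under Wald limits (over-flagging), 1.2% under exact
limits (less than half the nominal — under-flagging), and 2.0% under
prediction limits, which are the only ones whose tails are guaranteed
≤ 2.5% for every λ. Hence the package's default method for classification
is the conservative prediction limit.

Other entry points: `smrfunnel coverage-table` writes the full summary
table; `smrfunnel classify --providers providers.csv` flags a provider
table (CSV with header `provider_id,observed,expected`); `smrfunnel funnel`
writes plot-ready series, flags and an SVG figure; `smrfunnel simulate`
generates synthetic cohorts with known in-control/outlier structure. All
commands log their resolved parameters to stderr and accept `--config
FILE` with `key=value` lines.

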