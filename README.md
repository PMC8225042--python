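# msentropy

Multi-scale sample entropy (MSE) for single-channel time series, with
the systematic threshold bias of the classic algorithm made explicit
and correctable.

## The problem

MSE quantifies signal "complexity" by computing sample entropy
(SampEn) of a series after coarse-graining it at successive scales
τ = 1, 2, 3, …: non-overlapping blocks of τ samples are replaced by
their mean, and the series shortens to ⌊N/τ⌋.  SampEn(m, r) is the
negative log of the conditional probability that two length-m windows
matching within a Chebyshev tolerance r still match at length m + 1
(ordered pairs, self-matches excluded):

    SampEn(m, r) = −log( A^m(r) / B^m(r) )

The classic MSE recipe fixes r at 0.15 × SD of the *original* series
for every scale.  But block-averaging shrinks the SD of uncorrelated
input as σ/√τ, so a fixed tolerance admits ever more matches at larger
scales and entropy decays even when the irregularity of the process is
unchanged.  For unit-variance iid Gaussian noise the effect has a
closed form (entropies in nats):

    SampEn(τ, r) = −log erf( r·√τ / 2 )

which decreases monotonically in τ — a pure algorithmic artifact.  The
package implements three threshold policies side by side:

* **fixed** — the classic, biased algorithm (r from the scale-1 SD);
* **adaptive** — r recomputed from the SD of each coarse-grained
  series (the practical correction, valid for any signal);
* **analytic_gaussian** — r scaled by 1/√τ (the theoretical
  correction, exact for iid input).

It also ships closed-form and literal-quadrature Gaussian oracles,
seeded generators for the reference signals (Gaussian noise, 1/f
noise, random walk, ARIMA), a brute-force SampEn oracle, and a CLI.
Intended users: anyone applying MSE to physiological or other
time-series data who needs to know how much of a decaying entropy
curve is signal and how much is threshold artifact.

## Worked example

```python
import msentropy as me

ts = me.generate(me.SignalSpec(kind="gaussian", n=20_000, seed=1))
cmp = me.compare_modes(ts, me.MSEParams(m=2, r_factor=0.15))
print(cmp.to_frame()[["tau", "n_tau", "sd_tau", "entropy_fixed",
                      "entropy_adaptive", "bias"]].iloc[[0, 1, 3, 9, 19]])
```

prints (selected scales):

```
 tau  n_tau  sd_tau  entropy_fixed  entropy_adaptive   bias
   1  20000  1.0000         2.4674            2.4674 0.0000
   2  10000  0.7016         2.1151            2.4703 0.3552
   4   5000  0.4968         1.7717            2.4637 0.6920
  10   2000  0.3084         1.3301            2.4669 1.1368
  20   1000  0.2191         1.0105            2.5130 1.5025
```

Reading the table: the coarse-grained SD tracks 1/√τ (0.7016 ≈ 1/√2,
0.4968 ≈ 1/√4); the fixed-threshold entropy decays from 2.467 to 1.011
exactly as the closed form predicts (−log erf(0.075) = 2.4714 at
scale 1, 1.0086 at scale 20) although white noise is equally irregular
at every scale; the adaptive-threshold entropy stays flat near 2.47;
and the `bias` column — the entropy deficit the fixed threshold
introduces — matches the analytic prediction (e.g. 0.6920 measured vs
0.6875 predicted at τ = 4).

The same comparison from the shell:

```
mse compare --kind gaussian --n 20000 --seed 1 --scales 1:20 --out curve.tsv
mse theory --tau 1:20 --r 0.15 --out theory.tsv
mse figure1 --seed 1 --out-dir demo/   # three-signal demonstration
```

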