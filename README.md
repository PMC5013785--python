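# gradshift

Excitatory/inhibitory Gaussian generalization-gradient modelling of
olfactory conditioning data.

## The problem

When an animal is trained to respond to one odour (absolute conditioning, a
rewarded CS+) it also responds to similar odours — a generalization gradient
along a perceptual dimension such as aldehyde carbon-chain length. Training
it instead to discriminate (differential conditioning: a rewarded CS+ and a
punished CS− two carbons away) sharpens discrimination asymmetrically: the
response gradient's peak and mass shift away from the CS− (*peak shift* and
*area shift*). `gradshift` implements the analysis that explains this with
two interacting Gaussian gradients, for behavioural datasets of the kind
collected in harnessed-insect conditioning assays (binary
maxilla-labium/proboscis extension responses, four test odours per group).

## The model

The excitatory gradient is a Gaussian of fixed amplitude 100 centred on the
CS+,

    G_σ(x) = exp(−(x − c₊)² / (2σ²)),

read as the probability (in %) of responding to a stimulus at position *x*.
The inhibitory gradient G_σ′, centred on the CS−, is the probability of
being inhibited from responding. After differential conditioning the
response probability is the probability of being excited *and* not
inhibited, taken as independent events:

    R(x) = 100 · G_σ(x) · (1 − G_σ′(x)).

For each experiment, (σ, σ′) are fitted jointly by nonlinear least squares:
100·G_σ to the four absolute-conditioning response percentages and
R(x) to the four differential-conditioning percentages — a two-parameter
fit to eight points. Additive gradient-superposition variants
(clip(100·G_σ − A′·G_σ′, 0, 100) with A′ fixed at 100 or free) are provided
for model comparison, alongside peak/area-shift descriptors, the
paired-binary test statistics (Cochran's Q, McNemar with Holm correction,
Fisher's exact test) and a per-ant Bernoulli simulator of the whole design.

## Worked example

```python
import gradshift as gs

# simulate the four study designs (group sizes 29/38, 30/40, 30/41, 28/41)
fixture = gs.make_paper_fixture(seed=1)
for _, abs_t, diff_d, diff_t in gs.pair_records(fixture["records"]):
    fit = gs.fit_gradients(abs_t, diff_t, diff_d)
    peak = gs.peak_location(fit.model)
    print(f"{diff_d.experiment_id: <20} sigma={fit.sigma_hat:.3f} "
          f"sigma'={fit.sigma_prime_hat:.3f} peak_shift={peak - diff_d.cs_plus:+.3f}")
```

prints

```
hexanal+/octanal-    sigma=1.521 sigma'=1.012 peak_shift=-0.369
heptanal+/nonanal-   sigma=1.667 sigma'=1.351 peak_shift=-0.671
octanal+/hexanal-    sigma=1.564 sigma'=1.387 peak_shift=+0.648
nonanal+/heptanal-   sigma=1.563 sigma'=0.776 peak_shift=+0.176
```

Each line is one experiment: the fitted excitatory width σ and inhibitory
width σ′ (carbon units) and the displacement of the combined gradient's
peak from the CS+ — negative when the CS− sits above the CS+ and positive
when below, i.e. always *away* from the punished odour. The inhibitory
gradient comes out narrower than the excitatory one (σ′ < σ): punishment
acts more stimulus-specifically than reward.

The same analysis runs from the shell:

```sh
gradshift simulate --preset paper --seed 1 --out-dir out/
gradshift fit --input out/responses.csv --interaction all
gradshift stats --input out/per_ant.csv
gradshift run --config run.yaml        # end-to-end with a YAML config
```

To analyse real data, transcribe the response counts into the aggregate CSV
schema documented in `data/README.md` and point `gradshift fit`/`run` at it;
the scikit-learn estimator behind it all is
`gradshift.GradientCurveFitter(cs_plus=…, cs_minus=…).fit(X, y)` with X rows
of `(carbon_position, is_differential)` and y the observed percentages.

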