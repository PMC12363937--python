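# cipher

Predicting and attributing transcriptome-wide responses to genetic
perturbations from the gene–gene covariance of *unperturbed* cells.

Pooled single-cell CRISPR screens (Perturb-seq, CROP-seq) measure what
happens to the whole transcriptome when one gene is knocked down or
activated. Linear response theory says much of that answer is already
present before any perturbation: for a system fluctuating around a steady
state, the mean expression change under a small forcing `u` is

    ΔX = Σ u,

where `Σ` is the covariance of raw counts across unperturbed cells and
`ΔX = ⟨X⟩ᵤ − ⟨X⟩₀`. This package implements that framework for people who
analyze perturbation screens or build simulators of gene regulatory
networks:

- **Forward problem** — given the perturbed gene `i`, fit the optimal
  forcing `uᵢ* = ΣᵢᵀΔX / (ΣᵢᵀΣᵢ + ε)` and score the reconstruction with a
  masked `R² = 1 − ‖ΔX − Σu‖²/‖ΔX‖²` over responding genes; joint and
  additive models for double perturbations.
- **Inverse problem** — given only `Σ` and `ΔX`, infer which gene was
  perturbed: the decorrelated point estimate `u* = Σ⁻¹ΔX`, then sparse
  Bayesian refinement of the top-k candidates under a horseshoe prior
  (`uᵢ ~ N(0, λᵢ²τ²)`, `λᵢ ~ HalfCauchy(0,1)`, `ln τ ~ N(−4,1)`,
  `ln σ ~ N(−2,2)`) sampled with NUTS (8 × 1000 draws after 1000 tuning
  steps), with PIP / max-spread / logFC / rank-test rankings and pooled
  ROC evaluation.
- **Interpretation** — eigengenes (`Σ = VΛVᵀ`), response projections and
  participation ratios, per-gene contribution fractions
  `cᵢ = Σⱼ|Σᵢⱼuⱼ|`, entropy-based effective gene numbers, self-rank.
- **Null models** — mean-field (column-shuffled), fully shuffled, and
  ZINB variance-resampled covariances for ablation controls.
- **Simulators** — random linear networks with the exact Lyapunov
  covariance oracle, deterministic Hill networks with an analytic critical
  interaction, a stochastic bistable "teams" network of bursty promoters,
  and a labeled count-matrix fixture generator, so the whole pipeline is
  testable with no downloads.

Data comes in as `.h5ad` (AnnData) or MatrixMarket directories with
per-cell perturbation labels; everything is also usable directly from
Python on numpy arrays.

## Worked example

Generate a small synthetic screen with planted covariance structure, then
run the full pipeline (filter → covariance + nulls → forward fits →
Bayesian inverse → eigengene report):

```bash
cipher fixture --n-genes 40 --n-cells 200 --cells-per-perturbation 120 \
    --perturbations 3 --seed 3 --out fx.h5ad
cipher pipeline --input fx.h5ad --top-k 8 --chains 2 --tune 150 --draws 150 \
    --seed 6 --out-dir report
cat report/summary.json
```

prints (numbers from this exact invocation):

```json
{
  "auroc_logfc": 1.0,
  "auroc_max_spread": 1.0,
  "auroc_neg_log10_p": 1.0,
  "auroc_pip": 1.0,
  "auroc_u_magnitude": 1.0,
  "mean_participation_ratio": 5.485281139196257,
  "mean_r2_meanfield": 0.43027659065178253,
  "mean_r2_real": 0.9004400176649323,
  "mean_r2_shuffled": 0.43347373994691135,
  "n_perturbations": 3
}
```

Read: with the real covariance the forward fits reconstruct ~90% of each
perturbation's response energy; destroying the off-diagonal covariance
(mean-field or full shuffle) halves that, which is the whole point — the
predictive signal lives in the co-fluctuations. Every ranking metric
identifies the true targets perfectly on this fixture (AUROC 1.0), and an
average response occupies ~5.5 of 40 eigengene dimensions.
`report/per_perturbation.tsv` holds the per-perturbation R², participation
ratio, effective gene numbers, self-rank and the truth's rank shift during
inference.

The same steps are available as library calls
(`cipher.make_perturbation_fixture`, `cipher.estimate_covariance`,
`cipher.optimal_single_perturbation`, `cipher.horseshoe_inference`, ...);
see `docs/methods.md` for the model, priors, parameter defaults and
numerical conventions.

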