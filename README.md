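# phenoguide

Prediction-guided discovery of sepsis sub-phenotypes from ICU time series,
with treatment-policy evaluation per phenotype.

Sepsis is heterogeneous: unsupervised clustering of raw ICU measurements
tends to group patients by whatever dominates the input variance (age,
body size, vitals) rather than by clinically meaningful disease states.
`phenoguide` implements the *guided* alternative: a recurrent encoder is
trained to summarize each patient's 4-hour windows into a compact encoding
`z_t = g(x_{1..t})` while four auxiliary heads predict patient-centred
outcomes from `z_t` — 90-day mortality, remaining length of stay,
next-window renal replacement therapy, and next-window mechanical
ventilation — under a weighted aggregate loss

    L = w_m·BCE(ŷ_mort) + w_l·MSE(ŷ_los) + w_r·BCE(ŷ_rrt) + w_v·BCE(ŷ_mv).

The heads are deliberately small, so outcome-relevant structure must be
carried by the encoding. After training, K-means clusters the per-window
encodings of the validation split; K is selected by mean silhouette
`s(i) = (b_i - a_i)/max(a_i, b_i)` over K = 2..10. The resulting clusters
are the sub-phenotypes. Integrated Gradients
`IG_i = (x_i - x'_i)·(1/M)·Σ_m ∂F/∂x_i |_{x' + (m/M)(x - x')}`
attributes each encoding coordinate back to the input features per
cluster, and a tabular SARSA estimate of the behaviour policy's Q-function
`Q(s,a) ← Q(s,a) + α[r + γQ(s',a') - Q(s,a)]` — states are the phenotypes,
actions a 5×5 grid of IV-fluid volume × norepinephrine-equivalent
vasopressor rate, rewards ±100 on 90-day survival — quantifies how
observed treatment choices relate to outcomes within each phenotype.

Because the clinical databases this kind of analysis targets are
credentialed, the package ships a first-class synthetic ICU cohort
generator with six planted latent states (admission, renal, respiratory,
shock, recovering, partially recovered), realistic missingness, a
treatment behaviour policy with planted per-state optimal actions, and
ground-truth labels, so every stage — preprocessing, representation
learning, clustering, attribution, policy evaluation — is testable end to
end. See `docs/methods.md` for the model and simulator details.

The audience is methods researchers in clinical machine learning who want
a reproducible, fully inspectable reference implementation of the
guided-phenotyping recipe.

## Worked example

Run the full experiment on a 1,000-patient synthetic cohort:

```bash
phenoguide run --seed 0 --outdir runs/demo --verbose
```

which executes simulate → preprocess → train → cluster → attribute →
evaluate-policy → report and prints the run summary:

```json
{
  "k_selected": 6,
  "silhouette_at_k": 0.5207153702364916,
  "sarsa_exact_max_abs_diff": 0.008848060607197894,
  "auroc_mort": 0.8511163118092615,
  "auroc_rrt": 0.7713507343136973,
  "auroc_mv": 0.8044997155454416,
  "mse_los": 0.27286502615452285,
  "ari_vs_latent_val": 0.989937721917357
}
```

Reading this output: silhouette analysis over K = 2..10 selected six
sub-phenotypes (matching the six planted latent states; the adjusted Rand
index between the recovered clusters and the ground-truth states on the
validation split is 0.99, at a mean silhouette of 0.52). The guidance
heads reach test-split AUROCs of 0.85 (90-day mortality), 0.77 (next-window
RRT) and 0.80 (next-window MV), with a remaining-LOS mean squared error of
0.27 days². The SARSA Q-table agrees with exact policy evaluation on the
empirical MDP to 0.009 on the ±100 reward scale over well-visited
state-action pairs.

`runs/demo/` then contains the artifact CSVs: `cluster_assignment.csv`
(per patient-window phenotype), `cluster_summary.csv` (per-cluster
clinical-scale statistics and outcome rates), `transition_counts.csv`
(admission → phenotype → discharge/death flows), `attribution_map.csv`
(per-cluster feature attributions with direction flags), `q_table.csv`
(Q values, visit counts and optimal-region membership per state-action),
`metrics.json` (bootstrap CIs) and `manifest.json`. `phenoguide
show-config` prints every knob with its default; a YAML file passed via
`--config` overrides any subset.

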