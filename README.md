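# metabnet

Small-world analysis of longitudinal metabolic covariance networks from
in-vivo ¹H-MRS metabolite concentrations.

## The problem

Proton MRS quantifies a panel of brain metabolites (Cr, PCr, Glu, Gln, NAA,
…) in a voxel, repeatedly over time. Metabolites do not vary independently:
their concentrations co-vary across subjects, and that covariance structure
can be treated as a network — nodes are metabolites, edges are strong
inter-subject rank correlations. Graph statistics of this network
(integration, segregation, small-worldness) then quantify how a challenge
such as acute restraint stress reorganizes brain metabolism over time, at a
level no single-metabolite comparison can see.

`metabnet` implements that analysis end to end for tidy LCModel-style
tables `(group, subject, time_point, metabolite, concentration, crlb)`:

1. **QC** — keep metabolites with CRLB < 35 % at all time points; exclude
   subjects whose spectra fail on otherwise reliable metabolites.
2. **Network construction** — per (group, time point), the matrix of
   absolute Spearman correlations |ρ| across subjects; binarized over a
   threshold sweep (0.41–0.49, step 0.01).
3. **Backbone** — connections consistently present over time, selected per
   pair by a one-tailed sign test at α = 0.025 and aggregated by the
   minimum |ρ| across time points.
4. **Graph metrics** — global efficiency E_glob (mean inverse shortest
   path, 1/∞ = 0) and per-node local efficiency E_loc (efficiency of the
   neighbourhood-induced subgraph), compared with 1000 degree-matched
   Maslov–Sneppen rewirings:

       γ = E_glob / ⟨E_glob^rand⟩,   λ = ⟨E_loc⟩ / ⟨E_loc^rand⟩,
       σ = λ / γ  — the network is small-world when σ > 1.

5. **Group statistics** — each metric curve over the threshold sweep is
   summarized by its trapezoidal AUC; group differences are tested by
   permuting whole subjects between groups (1000 permutations), with the
   95th percentile of the null as the one-tailed critical value, a
   two-sided permutation p alongside, and Benjamini–Hochberg FDR across
   each comparison family.

A synthetic-cohort generator (Gaussian copula with designed per-time-point
Spearman templates, log-normal marginals, CRLB metadata) stands in for the
non-deposited in-vivo data: a "control" group with a Cr–PCr–Gln cluster and
a clustered background, and a "stress" group whose Cr links are removed and
whose clustered structure collapses at designated disrupted time points
while a Glu–NAA link persists. See `docs/methods.md` for the model, its
assumptions, and what the generator does *not* emulate.

## Worked example

```python
import metabnet as mn

cfg = mn.default_cohort_config(seed=42)          # 2 × 11 × 8 × 11 design
table = mn.generate_cohort(cfg)                  # 1936 tidy records
filtered, qc = mn.filter_by_crlb(table, crlb_threshold=35)

mat = mn.spearman_matrix(filtered, "control", 2, cfg.panel)
net = mn.binarize(mat, 0.41)
res = mn.small_worldness(net, n_random=1000, seed=7)
print(res.sigma, res.meets_criterion)
```

Output for the two groups at time point 2 (a disrupted time point),
threshold 0.41:

```
control: 12 edges  E_global=0.252  gamma=0.528  lambda=9.612  sigma=18.199  small-world=True
stress:  11 edges  E_global=0.480  gamma=1.096  lambda=0.871  sigma=0.795   small-world=False
```

The control network keeps its designed cliques — far higher local
efficiency than its rewired nulls (λ = 9.6) at the price of integration
(γ = 0.53), hence σ ≫ 1. The stress network at the disrupted time point is
statistically indistinguishable from (here slightly below) its own null
ensemble: σ < 1, no small-world organization.

Creatine's local-efficiency AUC, compared by whole-subject permutation
(n_perm = 1000) with BH correction across the three disrupted time points:

```
Cr E_local-AUC, time point 2: control=0.080 stress=0.000  p=0.056  p_fdr=0.168
Cr E_local-AUC, time point 3: control=0.080 stress=0.000  p=0.203  p_fdr=0.304
Cr E_local-AUC, time point 5: control=0.070 stress=0.029  p=0.578  p_fdr=0.578
```

The designed effect (stress loses Cr connectivity: AUC 0.08 → ~0) is
visible in the point estimates; with 11 subjects per group a single
cohort's permutation p-values are honestly noisy.

The same pipeline is scriptable from the shell:

```bash
metabnet simulate --seed 42 --out cohort.csv
metabnet qc --in cohort.csv --crlb-max 35 --out filtered.csv --report qc.json
metabnet build-network --in filtered.csv --group control --time 2 --out-prefix ctrl_t2
metabnet smallworld --net ctrl_t2_t0.41.tsv --n-random 1000 --seed 7
metabnet compare --in filtered.csv --metric local-eff --time 2 --metabolite Cr --n-perm 1000 --seed 11
metabnet run --config analysis.yaml --out results/   # full pipeline
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated cohorts, (t1) the empirical type-I error
of the SW-AUC permutation test under a true null — 200 replicate cohorts
whose two groups share one template, scored by the percentile critical-value
rule — and (t2) the mean fraction of metabolite pairs the strict-mode sign
test admits to the backbone when all metabolites are independent. Runtime
is ≈ 7 minutes on one CPU.
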