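# Methods

This note documents the models and numerical choices behind `metabnet`:
what is computed, under which assumptions, which knobs matter, and what the
bundled synthetic cohorts can and cannot establish.

## 1. Input model and quality control

The unit of data is a tidy record `(group, subject, time_point, metabolite,
concentration, crlb)` — the shape of an LCModel quantification export. All
analyses consume ranks of concentrations across subjects, so units
(institutional or mM) never matter downstream.

QC implements the CRLB < threshold inclusion rule (default 35 %, strict
inequality) at *all* time points. Because a CRLB table confounds "bad
subject" with "bad metabolite", the filter proceeds in three steps:

1. a metabolite whose CRLB fails for **more than half** of the subjects is
   a panel-level failure (never blamed on subjects);
2. a subject with any failing record on the remaining metabolites is
   excluded, with the offending metabolite/time point reported;
3. metabolite retention is re-tested on the surviving subjects.

The majority rule is the one free choice here; it reproduces the usual
workflow order (animals excluded first, the panel trimmed second) and
recovers injected ground truth exactly in the tests. The filter is
idempotent.

## 2. Network construction

For one (group, time point), the network is the M×M matrix of absolute
Spearman rank correlations of metabolite concentrations across subjects
(mid-rank ties; computed as the Pearson correlation of mid-ranks). The
absolute value is deliberate: the analysis studies an on/off connection
pattern, not signed coupling. Zero-variance metabolites yield undefined
correlations; these are set to 0 with a warning rather than erroring, so an
injected constant channel cannot kill a run.

Binarization keeps entries **strictly above** the threshold; the sweep
0.41–0.49 (step 0.01) produces nested edge sets. With continuous data the
strict/non-strict distinction has measure zero.

**Backbone.** For each pair, a one-tailed sign test over the T time points:
p = P(Bin(T, ½) ≥ k) where k counts time points supporting a connection;
eligibility requires p < α = 0.025. At T = 8 this effectively requires all
8 time points (k = 8 gives p = 1/256; k = 7 gives 9/256 > α). Two counting
modes exist because "supporting" is ambiguous for continuous data:

* `raw` (default): |ρ| > 0 — almost surely true, so eligibility is near
  universal and the *aggregated value* carries the selectivity;
* `strict`: |ρ| above the analysis threshold (0.41) — the mode used for the
  false-eligibility calibration.

Eligible pairs keep the **minimum** |ρ| across time (the most conservative
reading of "consistent connection"; median available via config). A
consequence used as a test invariant: backbone-then-binarize at t is always
a subset of the intersection of the per-time-point edge sets at t.

## 3. Graph metrics

Global efficiency is the Latora–Marchiori form: the mean of 1/d(i,j) over
node pairs with 1/∞ = 0. "Inverse of mean path length" is undefined for
disconnected graphs, which these sparse networks routinely are; the
mean-of-inverses form is bounded in [0,1] and maps an infinite path length
to zero contribution. Local efficiency of node i is the global efficiency
of the subgraph induced by i's neighbours (i excluded); degree < 2 gives 0.
Node averages run over **all** M nodes, isolated ones included.

The null model is Maslov–Sneppen double-edge-swap rewiring: degree
sequences are preserved exactly; swaps creating self-loops or multi-edges
are rejected and retried within a budget of 100× the target swap count
(10 swaps per edge by default — the standard mixing heuristic), after which
the current state is returned with an under-mixing warning. Ensemble
connectivity is *not* enforced; efficiency handles disconnection natively.
Small-worldness uses n_random = 1000 rewirings by default:

    γ = E_glob/⟨E_glob^rand⟩, λ = ⟨E_loc⟩/⟨E_loc^rand⟩, σ = λ/γ > 1.

σ > 1 alone is the criterion; γ and λ are reported but not gated (the
conventional companion conditions "γ ≈ 1, λ > 1" come with no tolerance).
If the ensemble's mean local efficiency is zero (very sparse graphs — all
rewirings triangle-free), σ is undefined: `small_worldness` raises
`UndefinedRatioError`; the pipeline records such a network as *not*
small-world with σ = NaN; inside permutation tests the permutation is
redrawn (below).

Kernels are numba JIT code over uint8 adjacency matrices with an inline
xorshift64* RNG (seeded via splitmix64 from the caller's 31-bit seed):
the swap loop is RNG-bound and runs ~10⁶ times per analysis. Results are
deterministic given seeds and platform-independent. The test suite checks
the kernels against brute-force Floyd–Warshall/induced-subgraph oracles on
every non-isomorphic graph with ≤ 6 nodes, and against networkx.

## 4. Group statistics

Metric curves over the sweep are summarized by trapezoidal AUC (exact for
the piecewise-linear curves plotted; units = metric × threshold-width, so
a constant σ = 1 over 0.41–0.49 has AUC 0.08).

The permutation test reallocates **whole subjects** to pseudo-groups of the
original sizes — a subject's entire longitudinal record moves together,
the only scheme consistent with reallocating "a set of concentrations in
each mouse". Both decision rules the literature uses are reported:

* the headline rule: observed difference (first group − second,
  alphabetical) against the 95th percentile of the permutation null
  (one-tailed, nominal type-I error 0.05);
* a two-sided p-value (1 + #{|null| ≥ |obs|})/(n_perm + 1).

A permutation whose metric evaluation is degenerate (σ undefined at some
threshold of the sweep) is redrawn and counted; more than 10 % redraws
aborts the comparison. In `run_full_analysis` an *observed* degenerate
metric (e.g. backbone σ when one group's backbone has ≤ 1 edge, which the
designed stress world produces on purpose) records the comparison under
`failed_comparisons` instead of aborting the run.

FDR families: SW comparisons across time points form one BH family;
E_local comparisons across metabolite × time point another; backbone
comparisons their own. Inside permutation metrics the σ ensemble uses
`n_random_perm` rewirings (default 100; 20 in the type-I calibration).
This is a compute knob, not a statistical one: the Monte-Carlo noise in σ
is common to observed and permuted statistics, so the test's level is
unaffected — only power is, mildly.

## 5. Synthetic cohorts: the stated world

Defaults: 2 groups × 11 subjects × 8 time points × 11 metabolites
(Ala, Cr, PCr, GABA, Glu, Gln, PCh, GSH, Ins, NAA, Tau). Concentrations
are drawn from a Gaussian copula whose correlation is the designed Spearman
template mapped through r = 2·sin(πρ_s/6), then pushed through log-normal
marginals with per-metabolite means at typical mouse-hippocampus values
(Glu 8.5, NAA 8.0, Tau 6.0, Ins 5.5, Cr 4.5, PCr 4.0, Gln 3.5, GABA 1.8,
GSH 1.3, Ala 0.8, PCh 0.6; units arbitrary) and a 15 % coefficient of
variation across subjects — a typical between-animal spread for LCModel
concentrations. Ranks are invariant to the marginal transform, so the
analysis sees exactly the designed dependence; concentrations are strictly
positive by construction. CRLB values are a constant 5 % baseline plus
explicitly injected failures; they do not feed back into concentration
noise.

**Template geometry is constrained by positive semidefiniteness.** A
sparse graph of strong correlations with zeros elsewhere is usually not a
valid correlation matrix: two 0.85-neighbours of one node force their
mutual correlation ≥ ~0.48. Templates are therefore disjoint
equicorrelated blocks, which are exactly PSD:

* **control**: triangles {Cr, PCr, Gln} (the designed cluster),
  {Glu, NAA, GSH}, {Ins, Tau, GABA} at strength 0.90; Ala and PCh carry no
  designed association (mirroring their lack of connections);
* **stress**: every Cr association removed at all time points; at the
  disrupted time points (default {2, 3, 5}) all clustered structure is
  dropped, leaving only Glu–NAA at 0.90 — so a Glu link persists into the
  backbone while clustering vanishes. (Adding Glu–Gln at full strength as
  well would force Gln–NAA ≈ strength², a designed triangle, contradicting
  the de-clustered intent — the PSD constraint again.)

Strength 0.90 keeps designed edges above the top threshold 0.49 with
probability ≈ 0.99 per time point at n = 11 (Fisher-z calculation), which
the min-aggregated backbone needs over 8 time points, and which "σ > 1 at
every control time point × threshold" requires. A conversion that is still
not PSD is repaired by eigenvalue clipping at 1e-8 and diagonal
renormalization; if any entry moves by more than 0.05 the template is
rejected as infeasible with the offending (group, time point) named.

Seeding: one master integer seed; every stochastic stage (each
(group, time point) draw, each permutation stream, each ensemble) derives
its own named stream via CRC32-keyed `numpy.random.SeedSequence` spawn
keys, so adding a stage never shifts another stage's draws and identical
configs give byte-identical outputs.

**What the generator does not emulate:** spectral fitting and its error
correlations (CRLB is metadata here, uncoupled from noise), within-subject
autocorrelation across time points (time points are independent draws),
group differences in means (only the dependence structure differs), and
any pharmacokinetic stress-hormone dynamics.

## 6. What a green test establishes — and two honest reds

The calibration studies validate *statistical levels*, not biology: the
permutation test's type-I error matches its nominal 5 % over 200 null
cohorts (measured 0.045 at seed 1), and strict-mode backbone eligibility
under full independence stays at ~0 ≪ α = 0.025.

Design recovery is qualitative. Over 20 seeds (n_random = 200): control
cohorts are small-world at **all** 8 × 9 (time point, threshold)
combinations in 18/20 seeds; the disrupted-period creatine effect
(stress mean Cr E_local-AUC below control) appears in 20/20 seeds.

Two stricter per-time-point assertions are kept in the acceptance suite
and fail by design, because they are statistically unattainable at
n = 11:

* *"stress loses σ > 1 at every disrupted time point"* — measured 4/20.
  Thresholded |Spearman| networks are intrinsically at least as clustered
  as their degree-matched rewirings: sample correlation matrices are
  positive semidefinite, so spurious edges arrive in triangles (a
  metabolite that spuriously correlates with one member of a strong pair
  correlates with the other too). Even an empty template yields
  P(σ ≤ 1 somewhere in the sweep) ≈ 0.5 per time point; no feasible
  correlation structure pushes that to the ~97 % a three-way conjunction
  needs. The lenient reading (≥ 1 disrupted time point failing) holds in
  16/20 seeds.
* *"stress Cr E_local-AUC below control at every disrupted time point"* —
  measured 11/20; occasionally creatine spuriously attaches to both ends
  of the strong Glu–NAA pair and momentarily shows E_local = 1. The
  disrupted-period mean comparison is the robust statement (20/20).

## 7. Known limitations

* n = 11 subjects puts an irreducible noise floor (SD ≈ 0.32) under every
  correlation estimate; single-cohort permutation p-values are noisy, and
  per-time-point binary contrasts are unreliable — compare AUCs over the
  disrupted period instead.
* The backbone sign test at T = 8 in raw mode is effectively an
  all-time-points rule; with T < 6 no pair can reach α = 0.025 and the
  backbone is empty by arithmetic.
* SW-AUC permutation comparisons at disrupted time points are frequently
  inevaluable (sparse permuted splits with degenerate null ensembles);
  such comparisons are reported as failed rather than silently imputed.
* Weighted networks, signed edges, partial correlations, and
  clustering/path-length small-worldness variants are out of scope.
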