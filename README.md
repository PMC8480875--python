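# methylnet

Hierarchy, control and perturbation analysis of epigenetic-clock methylation
networks.

DNA methylation at a few hundred CpG dinucleotides is enough to estimate a
person's age: a multi-tissue epigenetic clock maps beta values
*m<sub>i</sub>* ∈ [0, 1] to a "DNAm age" through

```
a = (a_t + 1) · Σ_i H_i m_i + a_t            if  Σ_i H_i m_i ≥ 0
a = exp(Σ_i H_i m_i + ln(a_t + 1)) − 1       otherwise
```

with clock coefficients *H* and adult threshold *a<sub>t</sub>* = 20.  The
clock CpGs do not vary independently: ageing drives coordinated changes across
the methylome.  `methylnet` treats the clock CpGs as an interacting system.
For a CpG-by-sample beta matrix it

1. **infers a directed signed network** by per-node Lasso-CV regression:
   *m<sub>j</sub>* = Σ<sub>i≠j</sub> β<sub>ji</sub> m<sub>i</sub> + β₀, with a
   link *i → j* of weight *w<sub>ij</sub>* = |β<sub>ji</sub>| per non-zero
   coefficient;
2. **sparsifies it** at the weight threshold *w\** maximising the efficiency
   quality function *J* = (*E<sub>g</sub>* + *E<sub>l</sub>*)/ρ<sub>L</sub>;
3. **quantifies hierarchy** via the *m*-reach (fraction of nodes reachable in
   ≤ *m* steps) and the Global Reaching Centrality
   GRC(*m*) = (1/(N−1)) Σ<sub>i</sub> [r<sub>m,max</sub> − r<sub>m</sub>(i)],
   judged against a degree-preserving link-randomised null ensemble;
4. **computes control centrality** *C(i)* — the number of nodes a single
   external signal at *i* can drive — by maximum bipartite matching on the
   reachable subgraph, plus its average ⟨c⟩ over a threshold sweep;
5. **propagates single-CpG perturbations** Δm = 2⟨σ(m)⟩ through walk-sum
   effective coefficients Σ<sub>ℓ≤ℓmax</sub> (B<sup>ℓ</sup>)<sub>ji</sub> and
   predicts the induced change Δa in clock age, together with the
   displacement geometry in methylation space (angle with **H**);
6. **ranks CpGs** by |Δa|, reach and ⟨c⟩ and reports top-*k* overlaps.

A synthetic-cohort generator with a planted sparse linear network, an age
signal and a fitted linear-branch clock makes every stage testable without any
data download.

## Worked example

```python
import methylnet as mn

cohort = mn.generate_cohort(n_cpgs=30, n_samples=600, edge_density=0.05,
                            coefficient_scale=0.4, noise_sd=0.02, seed=1)
model = mn.MethylationNetworkModel(cohort.matrix, cohort.clock)
results = model.fit(folds=10, seed=1)
print(results.summary())
hier = results.hierarchy(m=3, null_samples=1000, seed=1)
print(f"GRC(3) = {hier.grc:.3f}, null z = {hier.null.z_score:.2f}")
pert = results.perturbation(l_max=4)
print(f"mean |delta_a| at l_max=4: {pert['delta_a_abs'].mean():.2f} years")
top = pert['delta_a_abs'].idxmax()
print(f"most influential CpG: {top} ({pert.loc[top,'delta_a_abs']:.2f} years)")
```

prints

```
Methylation network results
===========================================
CpGs (nodes)                             30
Samples                                 600
CV folds / seed                      10 / 1
Links before threshold                  367
Mean total degree <k>                 24.47
Weight threshold w*                 0.07769
Links after threshold                    66
Link density rho_L                  0.07586
Efficiency J at optimum               6.374
===========================================
GRC(3) = 0.281, null z = -1.81
mean |delta_a| at l_max=4: 5.43 years
most influential CpG: cg000009 (15.97 years)
```

The summary block reports the inference scale (367 directed links before
thresholding, mean total degree ⟨k⟩ = 24.5), the efficiency-optimal threshold
and the surviving backbone of 66 links.  GRC(3) measures how top-heavy the
reach distribution is; the z-score compares it with 1,000 degree-preserving
randomizations (a randomly wired planted network need not be more hierarchical
than its null — on real cohorts the observed z is strongly positive).  The
perturbation numbers say how much the estimated age moves when one CpG is
shifted by twice the cohort's mean methylation spread and the change is allowed
to cascade through up to four links.

Real cohorts enter through `read_beta_matrix` (TSV/CSV, rows = CpGs) or
`read_geo_series_matrix` (GEO series-matrix export), with
`read_clock` supplying the clock coefficients; `run_full` orchestrates all
stages and writes every table, and the same pipeline is scriptable from the
shell:

```bash
methylnet simulate --n-cpgs 30 --n-samples 600 --seed 1 --outdir sim/
methylnet run-all --betas sim/betas.tsv --metadata sim/metadata.tsv \
    --clock sim/clock.csv --seed 1 --outdir out/
```

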