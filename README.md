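# uvbflav

Multi-omics analysis of UV-B / abscisic-acid (ABA) stress experiments in
plants: fast chlorophyll fluorescence (PAM parameters and the JIP-test),
OPLS-DA–based differential-metabolite screening with VIP scores,
differential gene expression on FPKM matrices, hypergeometric pathway
over-representation, and signed metabolite–transcript correlation
networks — plus a ground-truth synthetic-data generator that exercises
the whole chain.

The package is aimed at plant stress physiologists and computational
biologists who need a reproducible, scriptable version of the analysis
usually spread across instrument software, MetaboAnalyst-style web
tools and ad-hoc spreadsheets. The reference design is a three-treatment
experiment — `M` (PAR control), `N` (UV-B radiation), `Q` (UV-B + exogenous
ABA) — with three biological replicates per group, contrasts `MvsN`
(UV-B effect) and `NvsQ` (ABA effect on top of UV-B), and fold changes
expressed treatment-over-control.

## The statistics at the core

**PAM parameters.** Fv/Fm = (Fm − Fo)/Fm and Y(II) = (Fm′ − F)/Fm′,
summarised per group with one-way ANOVA, Tukey HSD and a compact-letter
display at α = 0.05.

**JIP-test.** From each fast fluorescence transient the landmarks
O (minimum), K (300 µs), J (2 ms) and P (maximum) are read on a
log-time grid; double normalizations
V<sub>t</sub> = (F<sub>t</sub> − F<sub>O</sub>)/(F<sub>P</sub> − F<sub>O</sub>) and
W<sub>t</sub> = (F<sub>t</sub> − F<sub>O</sub>)/(F<sub>J</sub> − F<sub>O</sub>)
give treatment-minus-control difference kinetics ΔV<sub>t</sub> and
ΔW<sub>t</sub>, whose reads ΔJ (at 2 ms) and ΔK (at 300 µs) diagnose
acceptor-side Q<sub>A</sub><sup>−</sup> accumulation and donor-side
(OEC) impairment.

**OPLS-DA.** A from-scratch single-response orthogonal PLS: the weight
w ∝ X′y defines one predictive component after y-orthogonal variation
is removed into n<sub>ortho</sub> components; inputs are
log2-transformed and mean-centered. Quality is R²Y in-sample and
Q² = 1 − PRESS/TSS from stratified cross-validation (leave-one-out for
small designs); Q² > 0.5 accepts the model, and a permutation test
provides the null. Feature importance is VIP with mean squared VIP = 1.

**Screens.** Differential flavonoids: VIP > 1 and FC ≥ 1.5 or ≤ 0.67 on
linear group means. Differential genes: Welch t on log2(FPKM+1),
Benjamini–Hochberg q < 0.05 plus a fold-change rule (default
|log2FC| ≥ 1).

**Enrichment & networks.** Upper-tail hypergeometric P(X ≥ k) per
pathway with BH adjustment; Pearson edges kept at r² ≥ 0.8 and p < 0.05
(exact t transform, df = n − 2), signed by the sign of r.

## Worked example

```python
import numpy as np
from uvbflav import (StudyDesign, simulate_metabolome, fit_opls,
                     cross_validated_q2, compute_vip, validate_model,
                     screen_dfs, tally_by_class)
from uvbflav.synth import random_planted_effects

design = StudyDesign(seed=11)                      # M, N, Q x 3 replicates
ids = [f"MET{i:05d}" for i in range(1, 2149)]
effects = random_planted_effects(ids, "MvsN", n_up=80, n_down=30,
                                 magnitude=2.0, rng=np.random.default_rng(11))
matrix, truth = simulate_metabolome(design, planted_effects=effects, cv=0.1)

groups = design.group_map()
samples = design.samples_of("M") + design.samples_of("N")
X, y = matrix[samples].T, groups.loc[samples].to_numpy()

model = fit_opls(X, y, n_ortho=1)                  # log2 + centering inside
q2 = cross_validated_q2(X, y, n_ortho=1, folds=7, seed=11)
print(f"R2Y = {model.r2y:.3f}, Q2 = {q2:.3f}, valid = {validate_model(q2)}")

vip = compute_vip(model).reindex(matrix.index)
hits = screen_dfs(matrix, groups, ("M", "N"), vip, classes=truth.classes)
up = (hits["direction"] == "up").sum(); down = (hits["direction"] == "down").sum()
print(f"{len(hits)} differential flavonoid candidates ({up} up, {down} down)")
print(tally_by_class(hits).head(4).to_string(index=False))
```

prints

```
R2Y = 1.000, Q2 = 0.991, valid = True
110 differential flavonoid candidates (80 up, 30 down)
     class  up  down  total
 flavanols   4     0      4
flavanones   1     1      2
  flavones   4     7     11
 flavonols   6     3      9
```

R²Y = 1 and Q² = 0.99 say the two treatment classes are perfectly
separated in-sample and almost perfectly under cross-validation — the
planted |log2FC| = 2 contrast is strong relative to the 10% replicate
noise, so the model is accepted (Q² > 0.5). The screen recovers the
110 planted effects (80 up, 30 down) with no false positives; the tally
splits the flavonoid-annotated hits by subclass and direction.

The same chain runs from the shell:

```sh
uvbflav run-all --seed 11 --out out/
uvbflav simulate --kind ojip --seed 2 --out data/
uvbflav ojip --traces data/ojip_traces.tsv --control M --treatment N --out out/ojip
```

`run-all` writes per-stage TSVs, a count ledger (`report.tsv`) and a
provenance-stamped `report.md`.

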