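# vcmnet

Candidate-gene discovery for cardiomyocyte maturation studies, plus the
functional-assay quantification needed to validate the candidates.

## What this is for

Ventricular cardiomyocytes differentiated from human embryonic stem cells
(hESC-VCMs) are electrically and contractilely immature compared with fetal
and adult ventricular cardiomyocytes. A classic route to finding the
regulators responsible is a staged expression study — undifferentiated hESC,
hESC-VCM, fetal-VCM, adult-VCM — analyzed with a weighted gene co-expression
network, followed by a filter cascade that narrows the most
maturation-relevant module down to a handful of chromatin-remodeler
candidates, and finally single-cell and engineered-tissue assays (Ca²⁺
imaging, patch clamp, optical mapping, cantilever force) that test what
those candidates do. `vcmnet` implements that whole computational chain as a
reusable, tested library, and ships seeded generators that emulate the
4-stage study design with known ground truth, so every step can be scored
against planted structure.

The analysis chain, in the field's standard notation:

* **Network.** Pearson correlations between gene profiles; unsigned power
  adjacency `a(i,j) = |cor(x_i, x_j)|^β` with β chosen for approximate
  scale-free topology (β = 9 is the conventional value for this design, and
  a `soft_threshold_scan` reports the fit R² per candidate power);
  topological overlap `TOM(i,j)`; clustering dissimilarity `1 − TOM` (or
  `1 − a`).
* **Modules.** Average-linkage hierarchical clustering with a deterministic
  tie-break, a static tree cut at a fraction of the maximum merge height,
  minimum module size 30, colors assigned largest-first (turquoise, blue,
  brown, …), unassigned genes grey; per-module eigengenes (first PC of the
  z-scored submatrix, sign-oriented).
* **Enrichment.** PCA with genes as observations; genes ranked by |loading|
  per component; module over-representation among the top-k genes by a
  one-degree-of-freedom Pearson chi-square,
  `χ² = (O−E)²/E + ((n−O)−(n−E))²/(n−E)`; generic annotation enrichment by
  hypergeometric upper tail (or resampling) with Bonferroni correction.
* **Prioritization.** module → transcriptional regulators → chromatin
  remodelers → differentially expressed in hESC-VCM vs either fetal- or
  adult-VCM (pooled t, BH q < 0.05, |log₂FC| ≥ 1) → standardized expression
  in hESC-VCM inside the closed window [0, +1]; survivors ranked by max
  |log₂FC|.
* **Assays.** Ca²⁺ pseudoratio `ΔF/F = (F − F_base)/(F_base − B)` with
  per-transient amplitude, 10%-to-peak upstroke time and 50%-decay time;
  action-potential amplitude, max dV/dt, APD50/APD90 (from the max-dV/dt
  instant), MDP, firing rate; force `F = k·δ` (cantilever) or
  `F = 3EI/L³·δ` (beam) with per-twitch force; conduction velocity from a
  least-squares plane fit of an activation-time map (`CV = 1/‖∇t‖`); qPCR
  fold change `2^(−ΔΔCt)`.

## Worked example

```
python analysis/01_simulate_study.py
python analysis/02_network_modules.py
python analysis/03_pca_enrichment.py
python analysis/04_prioritize_candidates.py
python analysis/05_functional_assays.py
```

On the default study (500 genes, 4 stages × 3 replicates, planted modules
of 120/80/50 genes, seed 11) this prints:

```
module sizes: {'grey': 142, 'turquoise': 141, 'blue': 112, 'brown': 105}
largest module is turquoise
PC1+PC2 explain 57.4% of variance
PC1 top-100: turquoise  observed  58 expected  28.2  chi2   43.86  p 3.53e-11
blue_published: chi2 = 11.11, p = 8.58e-04
turquoise_published: chi2 = 121.11, p = 3.62e-28
cascade survivor counts: {'module': 120, 'regulators': 42, 'remodelers': 12,
                          'de': 11, 'window': 2}
final candidates (by max |lfc|): ['G0330', 'G0268']
planted candidates recovered at ranks 1-2: True
```

Reading this: the tree cut recovers the three planted modules (the detected
turquoise covers 98% of the planted one; grey holds the unassigned noise
genes), the largest module dominates the top-100 PC1 loadings about twice
its background share (χ² = 43.9), the two published count tables reproduce
their χ² statistics of 11.11 and 121.11, and the filter cascade narrows 120
module genes to exactly the two planted chromatin-remodeler candidates,
ranked first by fold change. The assay step recovers a planted 0.8 ΔF/F
amplitude within ~2%, APD50/90 within ~1 ms, a 20 µN twitch force within
0.2% and an 80 mm/s conduction velocity within ~2%.

A small CLI covers the trace analyses: `analyze-calcium`, `analyze-ap`,
`analyze-force`, `analyze-map` (see `--help` on each; traces are two-column
time/value TSV or value-only with `--rate`).

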