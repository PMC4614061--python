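# postrest

Graph analysis of post-task resting-state functional connectivity.

`postrest` is a tested, reusable pipeline for ROI-level resting-state fMRI
acquired repeatedly under different task conditions (for example, resting
scans recorded after listening to emotionally different narratives). It asks
whether the intrinsic connectivity network reorganizes after a condition, and
where: which connections weaken, which nodes lose degree and strength, and
whether the change fades over the course of the scan.

The package covers the full chain from ROI time series to statistics:

- **Preprocessing** — initial-volume discard, head-motion QC (1.0 mm / 1.0°
  exclusion on the six rigid-body parameters), nuisance regression (linear
  trend, 6 motion parameters, white-matter and CSF signals), and an ideal
  0.01–0.08 Hz frequency-domain band-pass.
- **Connectivity** — pairwise Pearson correlation matrices per subject ×
  condition.
- **Network-based statistic (NBS)** — edgewise one-sided paired *t* tests; the
  connected components of edges with *t* ≥ τ are the candidate subnetworks,
  and family-wise error is controlled by sign-flip permutation of the
  per-subject difference matrices:
  *p*<sub>FWE</sub> = (1 + #{null max-component ≥ observed}) / (K + 1).
- **Graph construction** — connectedness-preserving sparsification: edges are
  recursively removed weakest-first, but an edge whose removal would
  disconnect the graph is retained and the next weakest removed instead, down
  to a target density; the density grid is 12–28 % in steps of 2 %.
- **Nodal metrics** — degree *k*ᵢ, strength *s*ᵢ, Onnela weighted clustering
  *C*ᵢ, local/global efficiency and their ratio (LEGE), weighted betweenness
  (normalized to [0, 1]), and the participation coefficient
  *P*ᵢ = 1 − Σ<sub>m</sub>(*s*<sub>im</sub>/*s*ᵢ)² over Louvain modules —
  plus the trapezoidal AUC of any metric across the density grid.
- **Group statistics** — Shapiro–Wilk normality gate, Friedman /
  Kruskal–Wallis omnibus tests, Wilcoxon signed-rank / Mann–Whitney post hocs,
  Bonferroni and Benjamini–Hochberg FDR corrections.
- **Dynamic analysis** — the cleaned series split into three nonoverlapping
  76-volume intervals, per-interval graphs at 18 % density,
  baseline-normalized degree/strength, and FDR-corrected paired tests per
  interval.
- **Connectivity-pattern analysis** — per-condition edge-consistency profiles
  of a focal node (fraction of subjects whose 18 %-density graph contains each
  edge, with an absolute ≥ 13-subject cut) and hypergeometric overlap
  probabilities against NBS subnetwork nodes.
- **Synthetic data** — a generator that emulates the study design (23
  subjects × 4 conditions, 104 ROIs, 240 volumes at TR 2.61 s) with community
  structure, a planted hub, a condition-specific 9-edge hub disconnection,
  AR(1) temporal autocorrelation and realistic nuisance contamination, so the
  whole pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from postrest import (SimulationSpec, nbs_permutation_test,
                      sparsify_grid, degree_and_strength)
from postrest.synthetic_data import simulate_clean_stacks

# a synthetic study with the default planted 9-edge hub disconnection
spec = SimulationSpec(conditions=("baseline", "dismissing"), seed=7)
stacks = simulate_clean_stacks(spec)

res = nbs_permutation_test(stacks["baseline"], stacks["dismissing"],
                           tau=4.0, n_permutations=2000, seed=7)
comp = res.largest_component
print(f"NBS baseline > dismissing at tau=4.0: "
      f"{comp.n_nodes} nodes / {comp.n_edges} edges, p_FWE = {res.p_fwe:.4f}")

planted = {tuple(e) for e in spec.effect_edges}
hit = len(planted & {tuple(e) for e in comp.edges})
print(f"planted subnetwork edges recovered: {hit}/{len(planted)}")

for cond in ("baseline", "dismissing"):
    degs = []
    for mat in stacks[cond].matrices:
        g = sparsify_grid(mat.values, [0.18])[0.18]
        degs.append(degree_and_strength(g)[0][spec.hub_index])
    print(f"hub degree at 18% sparsity, {cond}: {np.mean(degs):.1f}")
```

prints

```
NBS baseline > dismissing at tau=4.0: 9 nodes / 9 edges, p_FWE = 0.0015
planted subnetwork edges recovered: 9/9
hub degree at 18% sparsity, baseline: 26.6
hub degree at 18% sparsity, dismissing: 19.5
```

The permutation test isolates exactly the planted 9-node / 9-edge subnetwork
(*p*<sub>FWE</sub> ≈ 0.002), and the hub loses about seven edges of degree at
18 % density in the affected condition — the two signatures the downstream
group statistics then quantify.

There is also a CLI for file-based studies: `postrest simulate` writes a
synthetic study directory (atlas TSV, per subject × condition time-series,
SPM-style motion and nuisance files), and `postrest all --data <dir> --out
<dir>` (or any single stage: `qc`, `preprocess`, `connect`, `nbs`, `graphs`,
`metrics`, `dynamic`, `pattern`) runs the pipeline and writes TSV result
tables plus a machine-readable run log. The whole pipeline is a pure function
of (input files, config, seed).

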