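# rg4fret

Single-molecule FRET analysis of RNA G-quadruplex (rG4) folding dynamics.

RNA G-quadruplexes are four-stranded structures of stacked guanine quartets
stabilized by K⁺. In smFRET experiments a donor/acceptor pair flanking the
G-rich sequence reports its compaction: the proximity ratio
**E = I_A / (I_D + I_A)** is low for unfolded ssRNA and rises through the
partially folded G-hairpin and G-triplex intermediates to the fully folded
quadruplex. `rg4fret` implements the complete analysis used to resolve these
folding states and their K⁺- and helicase-dependent populations:

- **`rg4fret.synthetic`** — a ground-truth trace simulator: birth–death
  Markov dynamics over the folding pathway
  ssRNA ⇌ G-hairpin ⇌ G-triplex ⇌ G4, truncated-Gaussian FRET emission,
  donor/acceptor intensity noise, single-step photobleaching, and a
  Hill-type K⁺ dependence of the folding rates.
- **`rg4fret.traces`** — QC: proximity-ratio computation with background
  subtraction, change-point photobleach detection with channel attribution,
  truncation and molecule-level acceptance rules, and the 30–50
  frames-per-molecule selection for population histograms.
- **`rg4fret.hmm`** — K-state Gaussian-emission hidden Markov machinery:
  scaled forward/backward recursions, joint Baum–Welch over all traces of a
  condition, Viterbi idealization, and BIC state-count selection.
- **`rg4fret.population`** — population FRET histograms, multipeak Gaussian
  decomposition (EM with bounded widths and optional HMM-anchored centers),
  peak-area state fractions, K⁺ titration curves and before/after condition
  comparisons with molecule-level bootstrap confidence intervals.
- **`rg4fret.tdp`** — transition density plots, transition-count matrices,
  and detailed-balance asymmetry scores.
- **`rg4fret.binding`** — microscale thermophoresis (MST): normalized
  fluorescence (Fnorm, ‰) from laser-on/off windows, Hill dose-response
  fitting (EC50), and substrate affinity ranking.

## Worked example

Simulate a three-state construct (the G4-disabled mutant that stops at the
G-triplex), run the pipeline, and read off the recovered states:

```python
import rg4fret as r
from rg4fret.pipeline import analyze_condition

dataset = r.simulate_dataset(r.atrg3_model(), n_molecules=300, n_frames=500, seed=1)
result = analyze_condition(dataset.traces, n_states=3, seed=1)

print(result.qc["n_accepted"])            # 271
print(result.hmm_fit.model.means.round(3))  # [0.32  0.5   0.74 ]
print(result.decomposition.centers.round(3))  # [0.325 0.502 0.737]
print({k: round(v, 3) for k, v in result.fractions.items()})
# {'ssRNA': 0.359, 'G-hairpin': 0.318, 'G-triplex': 0.323}
```

271 of 300 molecules pass QC (the rest bleach too early or carry no active
FRET pair). The HMM recovers the three generating emission means
(0.32 / 0.50 / 0.74) and the three-peak Gaussian decomposition of the pooled
30–50-frame histogram lands on the same centers; the peak-area ratios give
roughly equal occupancy of the three states, matching the symmetric
generating kinetics.

The same stages are available from the shell:

```bash
rg4fret simulate --construct rg4 --kcl 10 --kcl 100 --kcl 400 --out sim/
rg4fret analyze --manifest sim/manifest.json --n-states 4 --out results/
rg4fret mst --curves curves.tsv --out mst/
```

`analyze` writes, per condition, a QC report, the fitted HMM, the idealized
trace segments, the FRET histogram and its Gaussian decomposition, and the
transition-density pairs; with several KCl conditions it also writes the
folded/unfolded titration table with bootstrap confidence intervals.

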