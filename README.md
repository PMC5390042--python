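# phytokappa

Statistical screening that links the phytochemistry of plant extracts to
their bioactivity. Given (i) an LC-MS feature table (one peak = one
*m/z* × retention-time pair, one intensity column per species), (ii)
replicate bioassay readings — agar-diffusion inhibition radii against a
bacterial tester strain and MTT absorbances for two mammalian cell lines
(HaCaT keratinocytes, IEC-6 intestinal epithelial cells) — and (iii) a
rooted phylogeny of the species, the package answers three questions:

1. **Which peaks track antimicrobial activity but not cytotoxicity?**
   Intensities are binarized (presence ⇔ intensity ≥ 10⁴), bioassays are
   binarized (active ⇔ mean inhibition radius ≥ 0.6 cm; cytotoxic ⇔
   BH-significant ANOVA vs. the solvent control at FDR α = 0.05 with mean
   viability < 100 %), and each peak profile is scored against each
   classification with Cohen's chance-corrected kappa,

   κ = (p_o − p_e) / (1 − p_e),

   with Fisher-exact p-values, Benjamini–Hochberg correction and
   competition ranks. The combined score

   κ̄_C = κ_AM − (κ_HaCaT + κ_IEC-6)

   rewards agreement with antimicrobial activity and penalises agreement
   with either cytotoxicity; a peak is *selected* as a candidate when
   κ̄_C ≥ 0.68 and κ_AM ≥ 0.68 (the "strong" tier; 0.35–0.67 is
   "moderate").

2. **Do peak *pairs* explain activity better than single peaks?** Every
   unordered pair of binary profiles is combined with Boolean AND
   (additivity/synergy proxy) and OR (functional-redundancy proxy) and
   re-scored; a pair *outperforms* when its κ exceeds the best individual
   κ. A blockwise Gram-matrix kernel evaluates the ~F²/2 pairs streaming,
   so full-scale screens (10⁹+ pairs) need per-pair O(n) counts and
   bounded memory.

3. **Is bioactivity phylogenetically clumped?** The Fritz–Purvis D
   statistic locates the observed sum of sister-clade differences between
   two permutation nulls (random tip shuffles, D ≈ 1, and Brownian-threshold
   evolution, D ≈ 0) with permutation p-values.

Because studies of this design rarely deposit the full feature matrix, a
first-class synthetic-data module generates complete studies — Yule trees,
clumped or random traits, triplicate bioassays, and feature tables with
planted causal peaks, planted AND-synergy pairs and planted OR-redundancy
pairs — so every stage is testable against known ground truth.

## Worked example

Run the full pipeline on a synthetic study (87 species, 2,000 peaks, 5 %
label-flip noise, one planted causal peak, one AND pair, one OR pair):

```python
from phytokappa.pipeline import PipelineConfig, run_pipeline
from phytokappa.synthetic_data import SyntheticConfig

config = PipelineConfig(
    out_dir="demo",
    simulate=SyntheticConfig(n_features=2000, flip_noise=0.05, seed=1),
    n_perm=1000,
    seed=1,
)
result = run_pipeline(config)
print(result.report["n_active"])          # {'AM': 17, 'HaCaT': 2, 'IEC-6': 22}
print(result.report["selected_features"])  # ['ft_01130']
print(result.report["dstat"]["AM"])
# {'d_obs': 15.647..., 'D': 0.1676..., 'p_random': 0.0, 'p_brownian': 0.312, ...}
```

17 of 87 species are classified antimicrobially active. The screen ranks
the planted causal peak (`ft_01130`, *m/z* 633.23 at 32.4 min) first with
κ_AM = 0.81 and κ̄_C = 0.88 — it is the only peak passing the selection
rule, exactly matching the planted ground truth in `demo/truth.json`.
Antimicrobial activity, simulated as a clade-concentrated trait, shows
phylogenetic clumping (D = 0.17, p_random < 0.001), while the random
cytotoxicity labels do not (D ≈ 1).

The AND pair screen evaluates all 1,999,000 pairs; its summary reports

```text
n_strong: 5    n_outperforming: 3    best_pair_kappa: 0.930
```

with the best pair combining the causal peak with one planted synergy
component (κ = 0.93 > 0.81, the best individual peak) — pairs beat single
peaks exactly where the generator planted interactions. Each summary also
carries a caveat that a maximum over ~F²/2 pairs exceeds the best of F
individual peaks even under the null.

The same stages are scriptable from the shell:

```bash
phytokappa simulate --seed 1 --out demo_inputs
phytokappa run --config config.yaml
phytokappa dstat --tree demo/tree.nwk --labels demo/labels.csv --assay AM
```

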