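# mitosig

Label-free optical metabolic imaging meets single-cell transcriptomics:
`mitosig` quantifies keratinocyte metabolic state in vitiligo skin from
two directions —

* **Mitochondrial clustering.** The NADH two-photon fluorescence texture
  of keratinocyte cytoplasm encodes mitochondrial organisation. The
  package fits the exponent β of the inverse power law

      R(k) = A · k^(−β)

  to the radially averaged power spectral density of an en-face image.
  High β ↔ fragmented mitochondria ↔ glycolysis-leaning cells; low β ↔
  fused networks ↔ OxPhos-leaning cells. Per-slice β over an epidermal
  z-stack gives a depth profile (high basal β, a spinous-layer minimum,
  recovery toward the stratum corneum in healthy skin); stacks are
  summarised by median β and β variability and compared between lesional
  and nonlesional skin with a linear mixed model
  (`metric ~ condition + (1|patient) + (1|site)`). Per-cell β
  distributions are summarised by a heterogeneity index (IQR/median).

* **Gene-signature scoring.** Per-cell signature scores with bin-matched
  control genes, a 21-metabolic-pathway enrichment scan against a
  stress-keratinocyte signature (Δscore vs Pearson correlation with the
  stress score, two-sided Wilcoxon rank-sum p), differential-expression
  counting within pathway universes (BH-FDR), and cell-state composition
  tables.

A synthetic-data subpackage generates spectral-oracle images (exact known
β), mechanistic mitochondrial textures (fragmentation sweeps, melanin
puncta, PSF blur, shot noise), z-stack cohorts with patient/site random
effects, and negative-binomial count matrices with a lesional-only stress
subpopulation — so every stage is testable without any data download.

Audience: imaging and single-cell researchers who need a reproducible,
scriptable reimplementation of this analysis for their own stacks and
count matrices, and methodologists who want the generators to benchmark
estimator behaviour.

## Worked example

```python
import numpy as np
from mitosig.synthetic.images import (SpectralImageSpec, StackTemplate,
                                      synth_spectral_image, synth_stack)
from mitosig.clustering import image_beta
from mitosig.profiles import stack_profile, locate_profile_minimum

# an image with known clustering exponent 1.5
img = synth_spectral_image(SpectralImageSpec(beta_true=1.5, seed=1))
est = image_beta(img, pixel_size=100 / 512)
print(est.beta, est.r_squared)        # 1.4997  0.99999995

# a nonlesional-template z-stack: depth profile and its minimum
stack = synth_stack(StackTemplate(n_slices=9, condition="nonlesional"),
                    SpectralImageSpec(beta_true=1.0, side_px=128), seed=4)
profile = stack_profile(stack)
print(round(profile.median_beta, 3),       # 1.148
      round(profile.beta_variability, 3),  # 0.399
      locate_profile_minimum(profile))     # 25.2  (um; mid-stack minimum)
```

The fitted exponent matches the programmed 1.5 to three decimals because
spectral synthesis imposes the power-law amplitude exactly; the stack's
smoothed profile puts its β minimum at 25.2 µm of 40 µm total depth — the
mid-stack (spinous-layer-like) minimum encoded by the nonlesional
template.

The same pipeline runs from the shell:

```bash
mitosig simulate cohort.yaml -o cohort/      # synthetic stacks + manifest
mitosig profile cohort/ -o profiles/         # per-stack depth profiles
mitosig compare profiles/profiles.csv -o out/  # mixed-model comparison
mitosig simulate expr.yaml -o expr/          # synthetic counts (MTX + TSV)
mitosig enrich expr/ -o enrichment/          # 21-pathway scan, DE, composition
```

Every run writes its resolved configuration (`resolved_config.yaml`) next
to the outputs; rerunning with the same spec and seed reproduces outputs
bit for bit.

## Layout

| module | contents |
| --- | --- |
| `mitosig.synthetic` | spectral/mechanistic image, stack, cohort and expression generators |
| `mitosig.clustering` | radial PSD, β fit, per-cell β, heterogeneity index |
| `mitosig.profiles` | depth profiles, spline smoothing, mixed-model comparisons |
| `mitosig.scoring` | normalisation, signature scores, Wilcoxon, enrichment scan, DE, composition |
| `mitosig.io` / `mitosig.cli` / `mitosig.config` | TIFF/MTX/GMT/CSV readers-writers, command line, run configuration |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
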