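# bcmoments

Moment feature vectors for protein domain structures, computed from
Gabor-filtered C-alpha distance matrices.

## The idea

The pairwise C-alpha distance matrix (DM) of a protein domain is a
grayscale texture image in which each secondary-structure element
leaves a characteristic low-distance pattern: an α-helix draws a strip
3–4 residues from and parallel to the main diagonal, a parallel β-sheet
a parallel strip further out, an anti-parallel sheet a strip
perpendicular to the diagonal, and tertiary packing contacts short
horizontal/vertical dashes. `bcmoments`:

1. convolves the DM with three oriented Gabor templates (t₁₃₅, t₄₅,
   t₀₊₉₀) and binarizes each response at ≤ 0, splitting the 135°
   response by distance to the diagonal, to obtain four **binary
   contact matrices** BCM_H, BCM_P, BCM_A, BCM_O (helix, parallel
   sheet, anti-parallel sheet, other contacts);
2. summarizes each BCM by its **composition moment**
   c = count₁ / (N(N−1)/2) (upper-triangle density) and by discrete
   **Legendre moments**

       λ_pq = (2p+1)(2q+1)/N² · Σᵢⱼ P_p(xᵢ) P_q(yⱼ) f(i,j),
       xᵢ = −1 + 2i/(N−1),

   keeping the 11 orders with p ≤ q and 1 ≤ p+q ≤ 5 per matrix;
3. assembles a **49-dimensional descriptor**: 4 composition moments +
   45 structural features (ln N plus 4 × 11 Legendre moments).

Downstream, the package provides a cross-validated classification
harness (SVM / random forest), a Gaussian kernel-PCA embedding whose
first three components form a 3-D "structure universe", and
Gaussian-kernel mean-shift clustering whose cluster count #C measures
structural variation. A synthetic-structure generator (ideal helices,
parallel/anti-parallel sheets, mixed α/β motifs, with configurable
noise) makes the whole pipeline testable without any downloads.

It is aimed at structural bioinformaticians who want a compact,
alignment-free structural descriptor for fold classification,
fold-space visualization, or structure retrieval.

## Worked example

```python
import numpy as np
from bcmoments import (SyntheticSpec, make_domain, make_dataset,
                       featurize, cross_validate, mean_shift_cluster)

trace = make_domain(SyntheticSpec("all_alpha", 60, noise_sd=0.0, seed=1))
vec = featurize(trace)
print({k: round(v, 3) for k, v in vec.as_dict().items()
       if k.startswith("comp_")})
# {'comp_H': 0.114, 'comp_P': 0.0, 'comp_A': 0.072, 'comp_O': 0.324}

dataset = make_dataset(n_per_class=25, noise_sd=0.2, seed=42)
X = np.array([featurize(t).values for _, t in dataset])
y = np.array([label for label, _ in dataset])
print(round(cross_validate(X, y, k=3, classifier="svm", seed=42), 3))
# 0.99
```

The composition moments say what the domain is made of: the all-α
domain has a helix density of 0.114 in its upper triangle, no parallel
sheet signal, and a large "other contacts" fraction from the packed
helix–helix interfaces. On the 100-domain synthetic benchmark (4 fold
classes, 0.2 Å coordinate noise) the 49-D descriptor recovers the class
of 99% of domains under 3-fold cross-validation.

The same pipeline is scriptable from the shell:

```sh
bcmoments --seed 3 simulate --n-per-class 25 --noise-sd 0.2 --outdir data/
bcmoments featurize 'data/*.trace.tsv' --out features.tsv
bcmoments --seed 3 classify features.tsv --labels data/labels.tsv --out report.json
bcmoments decompose data/all_alpha_0000.trace.tsv --outdir bcm/
```

## Layout

- `src/bcmoments/structure_io.py` — PDB / tabular C-alpha trace I/O
- `src/bcmoments/dm_bcm.py` — distance matrix, Gabor bank, binary contact matrices
- `src/bcmoments/moments.py` — composition + Legendre moments, 49-D assembly
- `src/bcmoments/synthetic_structures.py` — ideal SSE geometry generator
- `src/bcmoments/analysis.py` — classification, kernel-PCA, mean-shift
- `src/bcmoments/cli.py` — `bcmoments` command-line interface
- `docs/methods.md` — models, parameter choices, and limitations
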