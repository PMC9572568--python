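"""Generate the synthetic gin-and-tonic NIR design and inspect its layout.

The generator replicates the study design: 3 gin x 3 tonic brands, 20 pure
and 37 spiked drinks per combination (1.6-34.6 mg/L alprazolam), on the
10,000-4,000 cm^-1 grid at 4 cm^-1 steps.
"""

import numpy as np

from spikedspec import DesignSpec, generate_dataset, write_spectra

dataset = generate_dataset(DesignSpec(seed=1))
print(f"samples: {dataset.n_samples}  wavenumbers: {dataset.n_wavenumbers}")
print(f"pure: {(dataset.class_label == 'pure').sum()}  "
      f"spiked: {(dataset.class_label == 'spiked').sum()}")
print(f"spiking range: {dataset.concentration[dataset.concentration > 0].min():.1f}"
      f"-{dataset.concentration.max():.1f} mg/L")
print("per-combination counts:")
for combo in sorted(set(dataset.combination)):
    n = int(np.sum(dataset.combination == combo))
    print(f"  {combo}: {n}")

path = write_spectra(dataset, "synthetic_gin_tonic.csv")
print(f"wrote {path} (wide CSV: metadata columns, then wavenumbers descending)")
# 513 samples = 180 genuine + 333 spiked drinks; every downstream example
# starts from this table or regenerates it with the same seed.
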