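"""Apply the four candidate pre-treatments and see what each removes.

MC subtracts the training-mean spectrum; SNV+MC additionally removes
per-spectrum offset and scale; D1+MC / D2+MC replace spectra by smoothed
derivatives, suppressing baseline (D1) and slope (D2) effects.
"""

import numpy as np

from spikedspec import CANDIDATE_PIPELINES, DesignSpec, PreprocessingPipeline, generate_dataset

dataset = generate_dataset(DesignSpec(seed=1))
X, wn = dataset.absorbance, dataset.wavenumbers

for label in CANDIDATE_PIPELINES:
    pipe = PreprocessingPipeline(label)
    out = pipe.fit_transform(X, wn, dataset.sample_ids)
    print(f"{label:7s} -> shape {out.shape}, axis "
          f"{pipe.wavenumbers_out.max():.0f}-{pipe.wavenumbers_out.min():.0f} cm^-1, "
          f"RMS {np.sqrt(np.mean(out ** 2)):.3e}")
# The derivative pipelines drop 7 grid points at each end (edge shrink) and
# live on a much smaller numeric scale; mean-centered columns sum to zero.
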