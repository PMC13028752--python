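"""Measure cell deformability in one synthetic microfluidic image.

Renders a streamline background with 20 ground-truthed elliptical cells,
runs both image pipelines, and compares the recovered per-image mean
deformability index (DI) with the known truth.
"""

import numpy as np

import rbcdeform as r

config = r.PipelineConfig(criteria_units="micrometers")
background = r.BackgroundSpec(noise_sd=2.0)
image, truth = r.generate_image(background, n_cells=20, seed=42)

true_mean = float(np.mean(truth.true_dis))
print(f"ground truth: 20 cells, mean DI = {true_mean:.4f}")

for pipeline, runner in (("sine-window", r.run_sinewin), ("DoG", r.run_dog)):
    cells, summary = runner(image, config)
    print(
        f"{pipeline:12s} accepted {summary.n_cells:2d} cells, "
        f"DI_Total = {summary.DI_Total:.3f}, DI_Mean = {summary.DI_Mean:.4f}"
    )

# DI_Mean close to the generating mean shows the pipeline recovers the
# deformation of the rendered cells; the two pipelines differ slightly
# because they localize cell boundaries differently.
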