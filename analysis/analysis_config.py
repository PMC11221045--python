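"""Shared configuration for the numbered analysis drivers.

One synthetic study, analysed end to end: the generating selection
coefficients are the ground truth each stage's output is compared
against in the driver summaries.
"""

from pathlib import Path

from benthotrack.pipeline import PipelineConfig

OUT = Path("results/pipeline")

#: Generating selection (log RSS vs the reference substrate):
#: selection for mixed sediments with a veneer of mud, avoidance of
#: coarse sediments.
TRUE_BETA = {2: 0.8, 0: -0.4}

CONFIG = PipelineConfig(
    out_dir=str(OUT),
    reruns=100,
    per_individual=100,
    n_random_steps=50,
    bootstrap_reps=300,
    simulation=dict(
        n_individuals=5,
        n_steps=1500,
        beta=TRUE_BETA,
    ),
)
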