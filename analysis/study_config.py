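"""Shared configuration of the synthetic study driven by the numbered scripts.

One seed, one output directory: every script reads and writes
``results/pipeline`` so the sequence 01..07 reproduces the whole analysis.
"""

from hsp20pipe.config import PipelineConfig, SimulationParams

STUDY = PipelineConfig(
    seed=1,
    outdir="results/pipeline",
    bootstrap_replicates=1000,
    simulation=SimulationParams(seed=1),
)
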