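"""The reference synthetic study: cohort conditions and model profile.

This module pins down the end-to-end experiment the package documents and
its acceptance checks rerun: a nine-subject cohort with hemodynamic event
schedules (>= 3000 beats in total, strong amplitude+delay coupling of the
cardiac EIT component, moderate sensor noise) evaluated by
leave-one-subject-out cross-validation.

The model profile used here is the compact 1-D-over-frames variant of the
funnel CNN (kernel 12; filters 8, 4, 2; batch norm + ReLU; dense head)
trained for at most 15 epochs — sized so the whole study runs in minutes
on one CPU.  The 2-D variant with stride (2, 2) remains the library
default for :func:`eitbp.model.build_model`.
"""

from __future__ import annotations

from eitbp.model import ModelConfig
from eitbp.pipeline import PipelineResult, RunConfig, run_pipeline
from eitbp.synthdata import SimulationConfig

__all__ = ["reference_study_config", "run_reference_study"]


def reference_study_config(seed: int = 0, out_dir: str | None = None) -> RunConfig:
    """The frozen reference study configuration."""
    return RunConfig(
        simulation=SimulationConfig(),  # nine subjects, events enabled
        model=ModelConfig(
            conv_rank="1d",
            strides=((8, 8), (1, 1), (1, 1)),
            learning_rate=3e-3,
            epochs=15,
            early_stop_patience=5,
            batch_size=100,
        ),
        seed=seed,
        out_dir=out_dir,
    )


def run_reference_study(seed: int = 0, out_dir: str | None = None) -> PipelineResult:
    """Simulate, segment, train LOSO and evaluate the reference study."""
    return run_pipeline(reference_study_config(seed=seed, out_dir=out_dir))
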