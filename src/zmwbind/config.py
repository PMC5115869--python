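"""Run configuration: the pipeline's tunable constants with study defaults.

Defaults mirror the experimental constants of the study design: 10 Hz frame
rate (0.1 s frame period), 10 % donor cross-talk, 200 ms dead time, S/N
rejection threshold of 2, ligand concentrations 0.1-10 uM.  Configuration
files are YAML and round-trip exactly; concentrations may be given in uM
with the ``concentrations_uM`` key and are stored in molar.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


def split_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable hash rule).

    Stages can be rerun independently: the derived seed depends only on
    the master seed and the stage name.  Result is < 2**31.
    """
    h = np.random.SeedSequence(
        [int(master_seed)] + [ord(c) for c in stage]
    ).generate_state(1)[0]
    return int(h % (2**31))


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "process", "dwell", "fit", "rank", "report"]
    )
    frame_period: float = 0.1  # s
    crosstalk: float = 0.10
    dead_time: float = 0.2  # s
    snr_threshold: float = 2.0
    snr: float = 5.0  # simulated signal-to-noise ratio
    bleach_mean: float = 30.0  # s
    duration: float = 60.0  # s per molecule
    concentrations: list[float] = field(
        default_factory=lambda: [0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6]
    )  # molar
    n_per_conc: int = 100
    sim_model: int = 4
    fit_models: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7])
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if not (0 <= self.crosstalk < 1):
            raise ValueError("crosstalk must be in [0, 1)")
        if self.dead_time < 0 or self.snr_threshold < 0:
            raise ValueError("dead_time and snr_threshold must be >= 0")
        known = {"simulate", "process", "dwell", "fit", "rank", "report"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def stage_seed(self, stage: str) -> int:
        return split_seed(self.seed, stage)

    # -- persistence -------------------------------------------------------
    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "concentrations_uM" in doc:
            doc["concentrations"] = [float(c) * 1e-6 for c in doc.pop("concentrations_uM")]
        return cls(**doc)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
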