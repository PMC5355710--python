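"""Pipeline configuration: every tunable constant of the method in one place.

Defaults are the study-wide operating point: 40 Hz 3rd-order low-pass,
RLS order 3 with forgetting 0.99, 10-s epochs, the five rhythm bands on
the 0.1 Hz grid, AES constants (a=1, b=2.2, g=0.2/0.1/0.3), k=5 LPP
neighborhood, LSSVM regularization 100 and RBF width sigma^2=500,
combination weights (0.1, 0.9) / (0.02, 0.18, 0.8), structure-search grid
[1,15]^2 with tau=(0.8, 0.2), participant-A discretization coefficients,
and the unit-gain 0.2/0.8 threshold controller with a 2-step hold.

The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .performance import PARTICIPANT_Z
from .preprocess import DEFAULT_BANDS


@dataclass
class PipelineConfig:
    # signal conditioning
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    epoch_len: float = 10.0
    filter_cutoff: float = 40.0
    filter_order: int = 3
    rls_order: int = 3
    rls_lambda: float = 0.99
    # feature pipeline
    aes_a: float = 1.0
    aes_b: float = 2.2
    aes_gains: tuple = (0.2, 0.1, 0.3)
    lpp_neighbors: int = 5
    # classifier
    gamma_reg: float = 100.0
    sigma2: float = 500.0
    lssvm1_weights: tuple = (0.1, 0.9)
    lssvm2_weights: tuple = (0.02, 0.18, 0.8)
    grid: tuple = (1, 15)
    tau: tuple = (0.8, 0.2)
    variant: str = "lssvm2"
    orders: tuple | None = None
    # labels
    participant: str = "A"
    z: tuple = tuple(PARTICIPANT_Z["A"])
    # controller
    controller: str = "rule"
    controller_gain: float = 1.0
    controller_thresholds: tuple = (0.2, 0.8)
    set_point: float = 1.0
    hold_steps: int = 2
    # simulation
    sim_steps: int = 90
    sim_runs: int = 10
    # schedule
    schedule_counts: tuple = (1, 3, 4, 4, 3, 1)
    schedule_block_len: int = 90
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for YAML friendliness (restored on load)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        tuple_fields = {
            "aes_gains", "lssvm1_weights", "lssvm2_weights", "grid", "tau",
            "z", "controller_thresholds", "schedule_counts", "orders",
        }
        kwargs = {}
        for k, v in d.items():
            if k in tuple_fields and v is not None:
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)
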