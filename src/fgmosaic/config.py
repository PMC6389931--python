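"""Run configuration: schema validation, loading, and reproducible dumps."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import ParameterSet

__all__ = ["RunConfig", "TASKS", "FIXTURES"]

TASKS = ("equilibria", "branch1d", "diagram2d", "cycles", "regime", "simulate", "shift")
FIXTURES = ("mosaic", "hopf_nf", "bautin_nf")

#: Option keys accepted per task (beyond the common ones).
_TASK_OPTIONS: dict[str, set[str]] = {
    "equilibria": set(),
    "branch1d": {"param", "range", "step", "with_cycles"},
    "diagram2d": {"k_range", "nu_range", "seed_nu", "resolution"},
    "cycles": {"param", "range", "nu", "side"},
    "regime": {"k", "nu"},
    "simulate": {"state0", "t_span", "n_out"},
    "shift": {"t_perturb", "state_kick", "param_step", "initial_state"},
}


@dataclass
class RunConfig:
    """Validated configuration for one CLI run."""

    task: str
    fixture: str = "mosaic"
    params: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "fgmosaic_out"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.fixture not in FIXTURES:
            raise ValueError(f"unknown fixture {self.fixture!r}; expected one of {FIXTURES}")
        # parameter keys are validated by ParameterSet itself
        if self.fixture == "mosaic":
            ParameterSet.from_dict({**self.params})
        allowed = _TASK_OPTIONS[self.task]
        unknown = set(self.options) - allowed
        if unknown:
            raise ValueError(
                f"unknown option keys for task {self.task!r}: {sorted(unknown)} "
                f"(allowed: {sorted(allowed)})"
            )
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    @property
    def parameter_set(self) -> ParameterSet:
        return ParameterSet.from_dict(self.params)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = {"task", "fixture", "params", "options", "seed", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} (allowed: {sorted(known)})")
        return cls(**data)

    def dump(self, path) -> None:
        """Write the resolved config next to the outputs (reproducibility)."""
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
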