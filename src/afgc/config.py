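"""YAML run configuration shared by the CLI subcommands.

A config file has up to four blocks mirroring the pipeline stages::

    simulation:
      topology: dual_chain10
      seed: 1            # mandatory
      omega: 50
      alpha: 100
      sample_interval: 1.0
      t_end: 120
    preprocess:
      species: M
      smoothing_window_min: 60
      margin_min: 30
      min_length_h: 3.0
      paper_concat: false
    inference:
      method: plain      # or grouped
      order: 5
      threshold: 0.05
      bonferroni: true
      lam: null          # grouped only; null = select by criterion
      criterion: bic
    evaluation:
      variable: hours
      levels: [6, 14, 28]
      seeds: [0, 1, 2, 3, 4]

Unknown keys are rejected and all validation problems are reported at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .network_sim import SimulationParams

_SIM_EXTRA = {"topology", "n_cells", "kind_params", "network_seed", "noise_fraction"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationParams)} | _SIM_EXTRA
_PRE_KEYS = {"species", "smoothing_window_min", "margin_min", "min_length_h",
             "paper_concat"}
_INF_KEYS = {"method", "order", "threshold", "bonferroni", "lam", "criterion"}
_EVAL_KEYS = {"variable", "levels", "seeds", "hours", "base_seed", "topology",
              "sampling_interval", "method", "order", "noise_fraction",
              "alpha", "omega", "network_seed", "paper_concat", "n_cells"}


class ConfigError(ValueError):
    """Raised with every validation problem listed at once."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class RunConfig:
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        problems = []
        known_blocks = {"simulation", "preprocess", "inference", "evaluation",
                        "output_dir"}
        for key in raw:
            if key not in known_blocks:
                problems.append(f"unknown top-level key {key!r}")
        for block, allowed in (("simulation", _SIM_KEYS),
                               ("preprocess", _PRE_KEYS),
                               ("inference", _INF_KEYS),
                               ("evaluation", _EVAL_KEYS)):
            for key in raw.get(block) or {}:
                if key not in allowed:
                    problems.append(f"unknown key {key!r} in {block!r} block")
        sim = dict(raw.get("simulation") or {})
        if "seed" not in sim:
            problems.append("simulation.seed is mandatory")
        if problems:
            raise ConfigError(problems)
        return cls(simulation=sim,
                   preprocess=dict(raw.get("preprocess") or {}),
                   inference=dict(raw.get("inference") or {}),
                   evaluation=dict(raw.get("evaluation") or {}),
                   output_dir=raw.get("output_dir", "."))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def simulation_params(self) -> SimulationParams:
        kw = {k: v for k, v in self.simulation.items()
              if k not in _SIM_EXTRA}
        return SimulationParams(**kw)
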