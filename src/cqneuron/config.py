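"""Run configuration: a YAML-serialisable record of one CLI invocation.

CLI flags override config-file values; :meth:`RunConfig.to_yaml` /
:meth:`RunConfig.from_yaml` round-trip losslessly, which is covered by a
property test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .model import ModelParams, Variant

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    command: str = "equilibria"
    E: float = 70.0
    v: float = 3.0
    tau: float = 1.0
    variant: str = "autonomous"
    F: float | None = None
    omega: float | None = None
    W0: float = 0.0
    Z0: float = 0.0
    t_end: float = 200.0
    dt: float = 1.0e-3
    sweep: str | None = None  # "v" | "E" | "F" | "omega"
    sweep_min: float | None = None
    sweep_max: float | None = None
    sweep_step: float | None = None
    outdir: str = "."
    verbosity: int = 1

    def model_params(self) -> ModelParams:
        if self.variant == Variant.FORCED.value:
            return ModelParams(variant=Variant.FORCED, F=self.F, omega=self.omega)
        return ModelParams(E=self.E, v=self.v, tau=self.tau)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
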