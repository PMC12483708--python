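"""Serializable run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .diagnostics import DiagnosticsConfig
from .hmc import SamplerOptions
from .params import PriorConfig


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: data location, model size,
    priors, sampler settings and diagnostic thresholds."""

    data_path: str
    n_classes: int
    time_variable: str = "occasion"
    priors: str = "D10N50"
    lkj_shape: float = 2.0
    beta_sds: tuple = (10.0, 5.0, 5.0)
    resid_sd_scale: float = 5.0
    n_chains: int = 4
    warmup: int = 1000
    iters: int = 1000
    seed: int = 1
    target_accept: float = 0.8
    max_leapfrog: int = 1024
    init_step_size: float = 1.0
    window: int = 10
    min_run: int = 20
    di_threshold: float = 95.0
    di_run: int = 3
    trim_pct: float = 10.0
    output_dir: str = "gmmdiag_out"

    def prior_config(self) -> PriorConfig:
        return PriorConfig.from_label(
            self.priors, lkj_shape=self.lkj_shape,
            beta_sds=tuple(self.beta_sds),
            resid_sd_scale=self.resid_sd_scale)

    def sampler_options(self) -> SamplerOptions:
        return SamplerOptions(target_accept=self.target_accept,
                              max_leapfrog=self.max_leapfrog,
                              init_step_size=self.init_step_size)

    def diagnostics_config(self) -> DiagnosticsConfig:
        return DiagnosticsConfig(window=self.window, min_run=self.min_run,
                                 di_threshold=self.di_threshold,
                                 di_run=self.di_run, trim_pct=self.trim_pct,
                                 seed=self.seed)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["beta_sds"] = tuple(d.get("beta_sds", (10.0, 5.0, 5.0)))
        return cls(**d)
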