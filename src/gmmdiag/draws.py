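"""Container for posterior draws across chains, with CSV persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ClassParams, MixtureParams


def param_names(K: int) -> list[str]:
    """Column order: pi.k, beta0.k, beta1.k, beta2.k, sd_int.k,
    sd_slope.k, corr.k (k = 1..K), then sigma."""
    names = []
    for base in ("pi", "beta0", "beta1", "beta2", "sd_int", "sd_slope", "corr"):
        names.extend(f"{base}.{k + 1}" for k in range(K))
    names.append("sigma")
    return names


def params_to_row(params: MixtureParams) -> np.ndarray:
    cols = [params.pi,
            [cp.beta0 for cp in params.classes],
            [cp.beta1 for cp in params.classes],
            [cp.beta2 for cp in params.classes],
            [cp.sd_int for cp in params.classes],
            [cp.sd_slope for cp in params.classes],
            [cp.corr for cp in params.classes]]
    return np.concatenate([np.asarray(c, float) for c in cols]
                          + [[params.sigma_resid]])


def row_to_params(row: np.ndarray, K: int) -> MixtureParams:
    row = np.asarray(row, dtype=float)
    blocks = row[:7 * K].reshape(7, K)
    pi = blocks[0] / blocks[0].sum()  # renormalize tiny float drift
    classes = tuple(
        ClassParams(beta0=blocks[1][k], beta1=blocks[2][k], beta2=blocks[3][k],
                    sd_int=blocks[4][k], sd_slope=blocks[5][k],
                    corr=float(np.clip(blocks[6][k], -1.0, 1.0)))
        for k in range(K))
    return MixtureParams(pi=pi, classes=classes, sigma_resid=float(row[-1]))


@dataclass
class DrawsStore:
    """Kept draws of all model parameters across chains.

    ``params`` has shape (n_chains, n_iter, P) with columns named by
    :func:`param_names`; sampler series (log posterior, energy,
    divergence flags, leapfrog counts) run parallel to it.  ``metadata``
    records seeds, iteration counts, the prior label and backend settings
    so a run can be reproduced exactly.
    """

    n_classes: int
    params: np.ndarray                 # (n_chains, n_iter, P)
    lp: np.ndarray                     # (n_chains, n_iter)
    energy: np.ndarray | None = None
    divergent: np.ndarray | None = None
    n_leapfrog: np.ndarray | None = None
    at_max_leapfrog: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.params.ndim != 3:
            raise ValueError("params must be (n_chains, n_iter, P)")
        if self.params.shape[2] != 7 * self.n_classes + 1:
            raise ValueError("params width inconsistent with n_classes")
        pi = self.pi_draws()
        if np.any(pi < -1e-8) or np.any(np.abs(pi.sum(axis=-1) - 1) > 1e-6):
            raise ValueError("stored pi draws are not on the simplex")

    # ------------------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_iter(self) -> int:
        return self.params.shape[1]

    @property
    def columns(self) -> list[str]:
        return param_names(self.n_classes)

    def block(self, base: str) -> np.ndarray:
        """(n_chains, n_iter, K) array of one class-indexed parameter."""
        K = self.n_classes
        order = ("pi", "beta0", "beta1", "beta2", "sd_int", "sd_slope", "corr")
        if base == "sigma":
            return self.params[:, :, -1:]
        if base not in order:
            raise KeyError(base)
        i = order.index(base) * K
        return self.params[:, :, i:i + K]

    def pi_draws(self) -> np.ndarray:
        return self.block("pi")

    def draw(self, chain: int, iteration: int) -> MixtureParams:
        return row_to_params(self.params[chain, iteration], self.n_classes)

    def iter_draws(self, chain: int):
        for i in range(self.n_iter):
            yield self.draw(chain, i)

    def posterior_mean_params(self) -> MixtureParams:
        mean_row = self.params.reshape(-1, self.params.shape[2]).mean(axis=0)
        return row_to_params(mean_row, self.n_classes)

    # ------------------------------------------------------------------
    def to_chain_frame(self, chain: int) -> pd.DataFrame:
        df = pd.DataFrame(self.params[chain], columns=self.columns)
        df["lp__"] = self.lp[chain]
        if self.energy is not None:
            df["energy__"] = self.energy[chain]
        if self.divergent is not None:
            df["divergent__"] = self.divergent[chain].astype(int)
        if self.n_leapfrog is not None:
            df["n_leapfrog__"] = self.n_leapfrog[chain]
            # log2 scale of the trajectory length, as tree-based samplers
            # report it
            df["treedepth__"] = np.ceil(
                np.log2(np.maximum(self.n_leapfrog[chain], 1))).astype(int)
        if self.at_max_leapfrog is not None:
            df["treedepth_hit__"] = self.at_max_leapfrog[chain].astype(int)
        return df

    def save(self, directory) -> None:
        """Per-chain CSV files plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            self.to_chain_frame(c).to_csv(directory / f"chain_{c + 1}.csv",
                                          index=False)
        meta = dict(self.metadata)
        meta.update({"n_classes": self.n_classes, "n_chains": self.n_chains,
                     "n_iter": self.n_iter})
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "DrawsStore":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        K = meta["n_classes"]
        n_chains = meta["n_chains"]
        cols = param_names(K)
        params, lp, energy, divergent, nlf, cap = [], [], [], [], [], []
        for c in range(n_chains):
            df = pd.read_csv(directory / f"chain_{c + 1}.csv")
            params.append(df[cols].to_numpy())
            lp.append(df["lp__"].to_numpy())
            if "energy__" in df:
                energy.append(df["energy__"].to_numpy())
            if "divergent__" in df:
                divergent.append(df["divergent__"].to_numpy().astype(bool))
            if "n_leapfrog__" in df:
                nlf.append(df["n_leapfrog__"].to_numpy())
            if "treedepth_hit__" in df:
                cap.append(df["treedepth_hit__"].to_numpy().astype(bool))
        return cls(
            n_classes=K,
            params=np.asarray(params),
            lp=np.asarray(lp),
            energy=np.asarray(energy) if energy else None,
            divergent=np.asarray(divergent) if divergent else None,
            n_leapfrog=np.asarray(nlf) if nlf else None,
            at_max_leapfrog=np.asarray(cap) if cap else None,
            metadata={k: v for k, v in meta.items()
                      if k not in ("n_classes", "n_chains", "n_iter")},
        )
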