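"""Parameter and prior containers for growth mixture models."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_SIMPLEX_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Structural specification: number of classes and trajectory shape.

    The mean trajectory is polynomial in time of degree ``fixed_degree``
    (default quadratic); the random-effects design has exactly two
    columns, an intercept and a linear time slope.
    """

    n_classes: int
    fixed_degree: int = 2
    time_variable: str = "occasion"  # "occasion" (0..3) or "age" (age - 6)

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.fixed_degree != 2:
            raise ValueError("only quadratic mean trajectories are supported")


@dataclass(frozen=True)
class ClassParams:
    """Class-specific trajectory parameters.

    ``beta0 + beta1*t + beta2*t**2`` is the mean trajectory; ``sd_int``
    and ``sd_slope`` are the random intercept/slope standard deviations
    and ``corr`` their correlation.
    """

    beta0: float
    beta1: float
    beta2: float
    sd_int: float
    sd_slope: float
    corr: float

    def __post_init__(self):
        if self.sd_int < 0 or self.sd_slope < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("correlation outside [-1, 1]")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    @property
    def psi(self) -> np.ndarray:
        """Implied 2x2 random-effect covariance matrix (PSD)."""
        cov = self.corr * self.sd_int * self.sd_slope
        return np.array([[self.sd_int**2, cov], [cov, self.sd_slope**2]])

    def mean(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.beta0 + self.beta1 * t + self.beta2 * t**2


@dataclass(frozen=True)
class MixtureParams:
    """Full mixture parameter vector: class probabilities, per-class
    trajectory parameters, and the shared residual SD."""

    pi: np.ndarray
    classes: tuple[ClassParams, ...]
    sigma_resid: float

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(pi) != len(self.classes):
            raise ValueError("pi and classes length mismatch")
        if np.any(pi < -_SIMPLEX_TOL) or abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("pi is not on the simplex")
        if self.sigma_resid < 0:
            raise ValueError("sigma_resid must be >= 0")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def permuted(self, perm) -> "MixtureParams":
        """Relabel classes: new class k is old class perm[k]."""
        perm = list(perm)
        if sorted(perm) != list(range(self.n_classes)):
            raise ValueError("perm is not a permutation of 0..K-1")
        return MixtureParams(
            pi=self.pi[perm],
            classes=tuple(self.classes[p] for p in perm),
            sigma_resid=self.sigma_resid,
        )

    def canonical_order(self) -> "MixtureParams":
        """Reporting order: ascending class probability.

        Applied only when reporting, never during sampling.
        """
        perm = np.argsort(self.pi, kind="stable")
        return self.permuted(perm.tolist())


_LABEL_RE = re.compile(r"^D(?P<a>\d+(?:\.\d+)?)(?P<fam>[NC])(?P<s>\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class PriorConfig:
    """Prior configuration.

    * Dirichlet(alpha0, ..., alpha0) on the class probabilities;
    * half-normal or half-Cauchy with scale ``sd_scale`` on the random
      intercept/slope SDs of every class;
    * LKJ(lkj_shape) on each 2x2 random-effect correlation matrix
      (density proportional to (1 - rho^2)^(shape - 1));
    * independent zero-mean normals on the trajectory coefficients;
    * half-normal on the shared residual SD.

    The shorthand label follows the DdNs/DdCs convention, e.g. Dirichlet
    alpha0=10 with half-normal(50) SD priors renders as ``"D10N50"``.
    """

    alpha0: float = 10.0
    sd_family: str = "half-normal"  # or "half-cauchy"
    sd_scale: float = 50.0
    lkj_shape: float = 2.0
    beta_sds: tuple[float, float, float] = (10.0, 5.0, 5.0)
    resid_sd_scale: float = 5.0

    def __post_init__(self):
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.sd_family not in ("half-normal", "half-cauchy"):
            raise ValueError("sd_family must be 'half-normal' or 'half-cauchy'")
        if self.sd_scale <= 0 or self.lkj_shape <= 0 or self.resid_sd_scale <= 0:
            raise ValueError("scales and LKJ shape must be > 0")
        if len(self.beta_sds) != 3 or any(s <= 0 for s in self.beta_sds):
            raise ValueError("beta_sds must be 3 positive reals")

    @property
    def label(self) -> str:
        fam = "N" if self.sd_family == "half-normal" else "C"

        def num(x):
            return f"{int(x)}" if float(x).is_integer() else f"{x}"

        return f"D{num(self.alpha0)}{fam}{num(self.sd_scale)}"

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "PriorConfig":
        """Parse the DdNs/DdCs shorthand, e.g. ``"D10N50"`` or ``"D2C5"``."""
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValueError(f"unrecognized prior label {label!r}")
        fam = "half-normal" if m.group("fam") == "N" else "half-cauchy"
        return cls(alpha0=float(m.group("a")), sd_family=fam,
                   sd_scale=float(m.group("s")), **kwargs)
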