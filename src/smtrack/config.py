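"""Simulation configuration with schema validation.

A :class:`SimulationConfig` fully specifies the synthetic two-channel
acquisition: the K-state switching-diffusion model, optional per-state
confinement domains, localization noise, scripted inter-channel binding,
oligomer-dependent spot intensities, and photobleaching. Configs are
round-tripped through YAML; the packaged ``configs/default.yaml`` mimics a
TIRF single-molecule acquisition (30.5 ms frames, 300-frame movies,
0.3-0.6 particles/um^2).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "BindingParams",
    "IntensityParams",
    "SimulationConfig",
    "load_config",
    "save_config",
    "default_config",
]

_ATOL = 1e-12


class BindingParams(BaseModel):
    """Scripted binding of channel-2 particles to channel-1 particles."""

    k_on_script: float = Field(ge=0, description="binding events per free ch2 particle per s")
    mean_lifetime: float = Field(gt=0, description="mean bound lifetime tau_bind (s)")
    bound_offset_sd: float = Field(ge=0, description="per-axis SD of the bound-pair offset (um)")


class IntensityParams(BaseModel):
    """Oligomer-dependent spot intensity model.

    A spot of order n has mean ``n * mu1`` and SD ``sqrt(n) * cv1 * mu1``
    (independent emitters, shot-noise-like scaling).
    """

    mu1: float = Field(gt=0, description="monomer mean intensity (a.u.)")
    cv1: float = Field(gt=0, description="monomer coefficient of variation")
    oligomer_weights: list[list[float]] = Field(
        description="per-state simplex over orders 1..n_max"
    )

    @model_validator(mode="after")
    def _check_weights(self) -> "IntensityParams":
        for k, w in enumerate(self.oligomer_weights):
            arr = np.asarray(w, dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise ValueError(f"oligomer_weights[{k}] must be a non-empty vector")
            if (arr < 0).any():
                raise ValueError(f"oligomer_weights[{k}] has negative entries")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"oligomer_weights[{k}] must sum to 1 (got {arr.sum()})")
        return self


class SimulationConfig(BaseModel):
    """Ground-truth generative model for two-channel track sets."""

    n_states: int = Field(ge=1, description="number of diffusion states K")
    D: list[float] = Field(description="diffusion coefficient per state (um^2/s)")
    A: list[list[float]] = Field(description="per-frame row-stochastic transition matrix")
    pi: list[float] = Field(description="initial state distribution")
    confinement: list[Optional[float]] = Field(
        default=None,
        description="per-state square-domain edge L (um); null = free",
    )
    sigma_loc: float = Field(ge=0, description="localization noise SD per axis (um)")
    dt: float = Field(gt=0, description="frame interval (s)")
    n_frames: int = Field(ge=2, description="frames per movie")
    n_tracks: int = Field(ge=1, description="tracks per channel")
    field: float = Field(gt=0, description="edge length of the simulated area (um)")
    binding: Optional[BindingParams] = None
    intensity: Optional[IntensityParams] = None
    bleach_rate: float = Field(
        default=1.0, gt=0, le=1.0, description="per-frame survival probability"
    )
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="before")
    @classmethod
    def _default_confinement(cls, data):
        if isinstance(data, dict) and data.get("confinement") is None:
            k = data.get("n_states")
            if isinstance(k, int):
                data = dict(data)
                data["confinement"] = [None] * k
        return data

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        K = self.n_states
        D = np.asarray(self.D, dtype=float)
        if D.shape != (K,):
            raise ValueError(f"D must have length K={K}")
        if (D < 0).any():
            raise ValueError("all D must be >= 0")
        A = np.asarray(self.A, dtype=float)
        if A.shape != (K, K):
            raise ValueError(f"A must be {K}x{K}")
        if (A < 0).any() or np.abs(A.sum(axis=1) - 1.0).max() > _ATOL:
            raise ValueError("rows of A must be non-negative and sum to 1")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (K,) or (pi < 0).any() or abs(pi.sum() - 1.0) > _ATOL:
            raise ValueError("pi must be a length-K distribution")
        if len(self.confinement) != K:
            raise ValueError("confinement must have one entry per state")
        for L in self.confinement:
            if L is not None and L <= 0:
                raise ValueError("confinement L must be > 0 where present")
        if self.intensity is not None:
            if len(self.intensity.oligomer_weights) != K:
                raise ValueError("oligomer_weights must have one simplex per state")
        return self

    # -- convenience array views -------------------------------------------
    @property
    def D_arr(self) -> np.ndarray:
        return np.asarray(self.D, dtype=float)

    @property
    def A_arr(self) -> np.ndarray:
        return np.asarray(self.A, dtype=float)

    @property
    def pi_arr(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of A (left Perron eigenvector)."""
        w, v = np.linalg.eig(self.A_arr.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        return p / p.sum()


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.model_validate(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def default_config(**overrides) -> SimulationConfig:
    """The packaged default acquisition-mimicking configuration."""
    ref = importlib.resources.files("smtrack") / "configs" / "default.yaml"
    data = yaml.safe_load(ref.read_text())
    data.update(overrides)
    return SimulationConfig.model_validate(data)
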