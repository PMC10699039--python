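"""Run configuration: validated, defaulted, round-trippable.

A :class:`RunConfig` bundles every stage's parameters with a single global
seed. Stage seeds are derived deterministically from the global seed so
that toggling one stage never shifts another stage's random draws.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .sc import DIMS_GRID_DEFAULT, RES_GRID_DEFAULT, QCConfig
from .simulate import FlowSimConfig, ScSimConfig

__all__ = ["RunConfig", "StageToggles", "validate_config", "stage_seed", "demo_config"]

_STAGE_IDS = {"simulate": 0, "flow": 1, "cluster": 2, "sc": 3, "tcr": 4, "clonex": 5}

#: the 12 channels fed to unsupervised clustering: the checkpoint panel
#: plus the CD4/CD8 axes (FoxP3 stays out; the clusters should discover
#: the regulatory phenotype from checkpoint co-expression)
DEFAULT_CLUSTER_MARKERS = [
    "CD25", "CD28", "CD39", "4-1BB", "CTLA-4", "ICOS", "OX40", "PD-1",
    "PD-L1", "TIGIT", "CD4", "CD8",
]


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    flow: bool = True
    cluster: bool = True
    sc: bool = True
    tcr: bool = True
    clonex: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0, lt=2**31)
    outdir: str = "results/run"
    stages: StageToggles = Field(default_factory=StageToggles)

    flow_sim: FlowSimConfig = Field(default_factory=FlowSimConfig)
    sc_sim: ScSimConfig = Field(default_factory=ScSimConfig)
    qc: QCConfig = Field(default_factory=QCConfig)

    cluster_markers: list[str] = Field(default_factory=lambda: list(DEFAULT_CLUSTER_MARKERS))
    phenograph_k: int = Field(default=30, gt=0)
    umap: bool = False
    max_cluster_cells: int = Field(default=5000, gt=0)

    hvg_n: int = Field(default=3000, gt=0)
    dims_grid: list[int] = Field(default_factory=lambda: list(DIMS_GRID_DEFAULT))
    res_grid: list[float] = Field(default_factory=lambda: list(RES_GRID_DEFAULT))
    sc_knn_k: int = Field(default=20, gt=0)
    stability_floor: float = Field(default=0.5, ge=0, le=1)

    he_rule: str = "indicator-majority"
    lc_hc_min_cells: int = Field(default=10, gt=0)

    @field_validator("dims_grid")
    @classmethod
    def _dims_positive(cls, v):
        if any(d < 1 for d in v):
            raise ValueError("dims_grid entries must be >= 1")
        return v

    def with_seed(self, seed: int | None) -> "RunConfig":
        """Copy with the global seed (and derived stage seeds) replaced."""
        if seed is None:
            return self
        return self.model_copy(update={"seed": seed})


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    ss = np.random.SeedSequence([seed, _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; an empty file yields defaults.

    Unknown keys are rejected with a message naming them (pydantic strict
    extra handling); ``dump → validate`` round-trips identically.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **overrides}
    return RunConfig.model_validate(data)


def demo_config(**overrides) -> RunConfig:
    """Small end-to-end configuration: 2 patients × 2000 cells, narrow grids."""
    base = {
        "flow_sim": {"n_samples": 3, "cells_per_sample": 2000},
        "sc_sim": {"n_patients": 2, "cells_per_patient": 2000},
        "max_cluster_cells": 3000,
        "dims_grid": [5, 9, 13],
        "res_grid": [0.4, 0.8, 1.2],
    }
    base.update(overrides)
    return RunConfig.model_validate(base)
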