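"""Model specifications: which diffusion parameters depend on which factors.

A :class:`ModelSpec` declares, for each of the four diffusion parameters,
the design factors it is allowed to vary over (an empty list means one
global value), plus the boundary coding:

* ``stimulus`` coding — the boundaries are the two response alternatives
  (upper = "right"); the starting point then measures lateral response
  bias, and the drift rate is a magnitude whose sign follows the stimulus
  direction.
* ``accuracy`` coding — the boundaries are correct vs incorrect answers
  (upper = correct); the drift rate measures anticipation performance.

The catalogue reproduces the four modality models fitted to Experiment 1
(M1: nothing varies; M2: drift by modality; M3: non-decision time by
modality; M4: both) plus the Experiment 2 models: the stimulus-coded
manipulation check with the starting point per probability cue, the
accuracy-coded main model with drift, non-decision time and starting point
per congruency condition, and the stimulus-coded model that exactly
matches the synthetic generator (drift by congruency, starting point by
cue), used for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .generate import validate_trials

__all__ = ["ModelSpec", "MODEL_CATALOGUE", "build_model", "ModelData"]

PARAMS = ("v", "a", "z", "t")

_FIXED = MappingProxyType({"sv": 0.0, "sz": 0.0, "st": 0.0})


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of parameter-factor dependencies and boundary coding."""

    name: str
    boundary_coding: str = "stimulus"  # stimulus | accuracy
    depends: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=lambda: dict(_FIXED))
    description: str = ""

    def __post_init__(self) -> None:
        if self.boundary_coding not in ("stimulus", "accuracy"):
            raise ValueError(f"unknown boundary coding {self.boundary_coding!r}")
        for p in self.depends:
            if p not in PARAMS:
                raise ValueError(f"cannot declare dependencies for unknown parameter {p!r}")
        object.__setattr__(self, "depends", MappingProxyType({p: tuple(f) for p, f in self.depends.items()}))
        for p, val in self.fixed.items():
            if p in ("sv", "sz", "st") and val != 0.0:
                raise ValueError("intertrial variabilities are fixed at zero")

    @property
    def n_dependencies(self) -> int:
        return sum(len(f) for f in self.depends.values())

    def factors(self, param: str) -> tuple[str, ...]:
        return tuple(self.depends.get(param, ()))


MODEL_CATALOGUE: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in [
        ModelSpec("M1", "stimulus", {}, description="None"),
        ModelSpec("M2", "stimulus", {"v": ("modality",)},
                  description="Drift rate depends on the response modality"),
        ModelSpec("M3", "stimulus", {"t": ("modality",)},
                  description="Non-decision time depends on the response modality"),
        ModelSpec("M4", "stimulus", {"v": ("modality",), "t": ("modality",)},
                  description="Drift rate and non-decision time depend on the response modality"),
        ModelSpec("exp2_z_cue", "stimulus", {"z": ("cue",)},
                  description="Manipulation check: starting point depends on the probability cue"),
        ModelSpec("exp2_main", "accuracy",
                  {"v": ("congruency",), "t": ("congruency",), "z": ("congruency",)},
                  description="Drift rate, non-decision time and starting point depend on congruency"),
        ModelSpec("exp2_generative", "stimulus", {"v": ("congruency",), "z": ("cue",)},
                  description="Drift rate depends on congruency, starting point on the cue"),
    ]
}


class ModelData:
    """Trial data recoded and indexed for one :class:`ModelSpec`.

    Holds, per subject, the response times, upper-boundary indicators,
    drift signs, and for each parameter the cell index of every trial plus
    the trial subsets belonging to each cell.
    """

    def __init__(self, spec: ModelSpec, trials: pd.DataFrame):
        validate_trials(trials)
        if len(trials) == 0:
            raise ValueError("trial table is empty")
        self.spec = spec
        trials = trials.reset_index(drop=True)
        if spec.boundary_coding == "accuracy":
            hit_upper = trials["correct"].to_numpy(dtype=bool)
            sign = np.ones(len(trials))
        else:
            hit_upper = (trials["response"] == "right").to_numpy()
            sign = np.where(trials["stimulus"] == "right", 1.0, -1.0)

        self.subjects = sorted(trials["subject"].unique())
        self.cells: dict[str, list[str]] = {}
        cell_idx_cols: dict[str, np.ndarray] = {}
        for p in PARAMS:
            factors = spec.factors(p)
            for f in factors:
                if f not in trials.columns:
                    raise ValueError(f"factor {f!r} required by parameter {p!r} is not a column")
                if trials[f].nunique() < 2:
                    raise ValueError(
                        f"factor {f!r} is degenerate (single level {trials[f].iloc[0]!r}); "
                        f"drop the dependency for parameter {p!r}"
                    )
            if factors:
                key = trials[list(factors)].astype(str).agg(":".join, axis=1)
                levels = sorted(key.unique())
                self.cells[p] = levels
                lut = {lab: i for i, lab in enumerate(levels)}
                cell_idx_cols[p] = key.map(lut).to_numpy(dtype=np.int64)
            else:
                self.cells[p] = ["all"]
                cell_idx_cols[p] = np.zeros(len(trials), dtype=np.int64)

        self.rt: list[np.ndarray] = []
        self.hit_upper: list[np.ndarray] = []
        self.sign: list[np.ndarray] = []
        self.cell_idx: list[dict[str, np.ndarray]] = []
        self.subsets: list[dict[tuple[str, int], np.ndarray]] = []
        empty_cells = []
        subj_codes = trials["subject"].to_numpy()
        for s in self.subjects:
            mask = subj_codes == s
            self.rt.append(trials.loc[mask, "rt"].to_numpy(dtype=float))
            self.hit_upper.append(hit_upper[mask])
            self.sign.append(sign[mask])
            cidx = {p: cell_idx_cols[p][mask] for p in PARAMS}
            self.cell_idx.append(cidx)
            subs = {}
            for p in PARAMS:
                for ci, label in enumerate(self.cells[p]):
                    idx = np.flatnonzero(cidx[p] == ci)
                    if len(idx) == 0:
                        empty_cells.append(f"subject {s}, {p}[{label}]")
                    subs[(p, ci)] = idx
            self.subsets.append(subs)
        if empty_cells:
            raise ValueError("design cells without trials: " + "; ".join(empty_cells))
        self.n_trials = len(trials)
        self.data_hash = int(
            pd.util.hash_pandas_object(
                trials[["subject", "rt", "response", "stimulus", "correct"]], index=False
            ).sum()
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def min_rt(self, subject_index: int) -> float:
        return float(self.rt[subject_index].min())


def build_model(spec: ModelSpec | str, trials: pd.DataFrame) -> ModelData:
    """Recode and index ``trials`` for ``spec`` (catalogue name or instance)."""
    if isinstance(spec, str):
        try:
            spec = MODEL_CATALOGUE[spec]
        except KeyError:
            raise KeyError(
                f"unknown model {spec!r}; catalogue: {sorted(MODEL_CATALOGUE)}"
            ) from None
    return ModelData(spec, trials)
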