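"""Shared result containers: model fits and per-visit prediction sets."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .panel import Gender

__all__ = ["FitResult", "PredictionSet"]


@dataclass
class FitResult:
    """Outcome of fitting one model to one cohort.

    ``params`` is the model's parameter object (TransitionParams or
    LMEParams); ``se`` maps parameter names to standard errors; ``loglik`` is
    the maximized log-likelihood used for information criteria (for mixed
    models the ML value, with the REML criterion kept in ``extras``).
    """

    params: Any
    se: dict[str, float]
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    model: str
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "model": self.model,
            "params": _params_dict(self.params),
            "se": {k: _num(v) for k, v in self.se.items()},
            "loglik": _num(self.loglik),
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "extras": {k: _num(v) for k, v in self.extras.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @staticmethod
    def from_json(path: Union[str, Path]) -> "FitResult":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        params = _params_from_dict(payload["params"])
        return FitResult(
            params=params,
            se=payload["se"],
            loglik=payload["loglik"],
            n_obs=payload["n_obs"],
            n_params=payload["n_params"],
            converged=payload["converged"],
            n_iter=payload["n_iter"],
            model=payload["model"],
            extras=payload.get("extras", {}),
        )


def _num(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _params_dict(params: Any) -> dict:
    d = dataclasses.asdict(params)
    d["_type"] = type(params).__name__
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = [_num(x) for x in v]
        else:
            d[k] = _num(v)
    return d


def _params_from_dict(d: dict) -> Any:
    from .mixed import LMEParams
    from .transition import TransitionParams

    kind = d.pop("_type")
    cls = {"TransitionParams": TransitionParams, "LMEParams": LMEParams}[kind]
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)


@dataclass
class PredictionSet:
    """Per-visit one-step-ahead predictions paired with the observed values.

    ``data`` holds one row per (donor_id, visit) with columns ``y_pred`` and
    ``y_obs`` (both mmol/l); ``gender`` selects the clinical cut-off for
    eligibility classification; ``model`` is a display label.
    """

    data: pd.DataFrame
    gender: Gender
    model: str = ""

    def __post_init__(self) -> None:
        required = ["donor_id", "visit", "y_pred", "y_obs"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"prediction frame missing column(s): {missing}")
        self.data = (
            self.data.loc[:, required]
            .sort_values(["donor_id", "visit"], kind="mergesort")
            .reset_index(drop=True)
        )
        if self.data.duplicated(["donor_id", "visit"]).any():
            raise ValueError("duplicate (donor_id, visit) entries in prediction set")
        vals = self.data[["y_pred", "y_obs"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite prediction or observation")
        self.gender = Gender(self.gender)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.assign(gender=self.gender.value, model=self.model).to_csv(
            path, index=False
        )

    @staticmethod
    def from_csv(path: Union[str, Path]) -> "PredictionSet":
        df = pd.read_csv(path, dtype={"donor_id": str})
        gender = Gender(df["gender"].iloc[0]) if "gender" in df else Gender.male
        model = str(df["model"].iloc[0]) if "model" in df else ""
        return PredictionSet(df, gender=gender, model=model)
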