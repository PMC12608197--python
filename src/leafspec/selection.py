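"""Shared containers for wavelength-selection results and population traces."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SelectionResult", "PopulationTrace"]


@dataclass
class PopulationTrace:
    """Per-iteration bookkeeping of a model-population selector.

    ``subset_sizes`` and ``rmsecv`` are parallel per-iteration records;
    ``weights`` optionally holds the final per-channel weight/frequency
    vector.  Suitable for plotting RMSE_CV-versus-iteration curves.
    """

    subset_sizes: np.ndarray
    rmsecv: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.subset_sizes = np.asarray(self.subset_sizes, dtype=int)
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        if self.subset_sizes.shape != self.rmsecv.shape:
            raise ValueError("trace arrays must have equal length")
        if self.rmsecv.size and np.any(self.rmsecv[np.isfinite(self.rmsecv)] < 0):
            raise ValueError("RMSE_CV values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.rmsecv.size + 1),
                "subset_size": self.subset_sizes,
                "rmsecv": self.rmsecv,
            }
        )


@dataclass
class SelectionResult:
    """A selected channel-index subset with provenance.

    ``channels`` index into the 646-channel modeling window.  Chained stages
    (coarse -> fine -> optimal) must select subsets of their parent; the
    constructor enforces sortedness, uniqueness and chain containment.
    """

    channels: np.ndarray
    stage: str  # coarse | fine | optimal
    algorithm: str
    seed: int
    trace: Optional[PopulationTrace] = None
    parent: Optional["SelectionResult"] = None
    best_rmsecv: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        channels = np.unique(np.asarray(self.channels, dtype=int))
        if channels.size and channels[0] < 0:
            raise ValueError("negative channel index")
        if self.parent is not None:
            if not np.isin(channels, self.parent.channels).all():
                raise ValueError(
                    f"{self.stage} selection is not a subset of its "
                    f"{self.parent.stage} parent"
                )
        self.channels = channels

    @property
    def n_selected(self) -> int:
        return int(self.channels.size)

    def chain(self) -> list["SelectionResult"]:
        """This result and its ancestors, outermost stage first."""
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": self.channels.tolist(),
            "stage": self.stage,
            "algorithm": self.algorithm,
            "seed": self.seed,
            "best_rmsecv": self.best_rmsecv,
            "parent": None
            if self.parent is None
            else {
                "channels": self.parent.channels.tolist(),
                "stage": self.parent.stage,
                "algorithm": self.parent.algorithm,
                "seed": self.parent.seed,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        parent = None
        if d.get("parent"):
            p = d["parent"]
            parent = cls(
                channels=np.array(p["channels"], dtype=int),
                stage=p["stage"],
                algorithm=p["algorithm"],
                seed=int(p["seed"]),
            )
        return cls(
            channels=np.array(d["channels"], dtype=int),
            stage=d["stage"],
            algorithm=d["algorithm"],
            seed=int(d["seed"]),
            best_rmsecv=d.get("best_rmsecv"),
            parent=parent,
        )
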