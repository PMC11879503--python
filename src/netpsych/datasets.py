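"""The questionnaire dataset container used by every analysis stage.

A :class:`QuestionnaireDataset` is a complete-case rectangular table of
per-participant subscale scores (rows = participants, columns = nodes),
optionally carrying a community label per node (the instrument each
subscale belongs to, e.g. SPQ / ERQ / DASS) and categorical grouping
columns per participant (gender, age band, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class QuestionnaireDataset:
    """Participants x subscale-score matrix with optional group labels.

    Parameters
    ----------
    scores
        Numeric ``n x p`` DataFrame; one row per participant, one column
        per subscale node.  Must be complete (no missing values) and every
        column must vary.
    communities
        Map from node name to community label.  May be empty when no
        community structure is relevant (e.g. pure DAG simulations).
    groups
        Optional DataFrame of categorical per-participant labels, aligned
        row-by-row with ``scores``.
    """

    scores: pd.DataFrame
    communities: dict[str, str] = field(default_factory=dict)
    groups: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("scores contain missing values; complete cases required")
        variances = self.scores.var(axis=0, ddof=1)
        dead = list(variances.index[variances <= 0])
        if dead:
            raise ValueError(f"constant column(s): {dead}")
        if self.communities:
            missing = [c for c in self.scores.columns if c not in self.communities]
            if missing:
                raise ValueError(f"nodes without a community label: {missing}")
        if self.groups is not None and len(self.groups) != len(self.scores):
            raise ValueError("groups not aligned with scores")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    @property
    def node_names(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "QuestionnaireDataset":
        """Row-subset by boolean mask or integer index array."""
        scores = self.scores.iloc[mask].reset_index(drop=True)
        groups = None
        if self.groups is not None:
            groups = self.groups.iloc[mask].reset_index(drop=True)
        return QuestionnaireDataset(scores, dict(self.communities), groups)

    def split_by(self, column: str) -> dict[str, "QuestionnaireDataset"]:
        """Split into one dataset per level of a grouping column."""
        if self.groups is None or column not in self.groups.columns:
            raise KeyError(f"no grouping column {column!r}")
        out = {}
        for level in self.groups[column].unique():
            mask = (self.groups[column] == level).to_numpy()
            out[str(level)] = self.subset(mask)
        return out

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, ground_truth: dict | None = None) -> None:
        """Write scores (+ group columns) as CSV; optional sidecar JSON.

        The sidecar ``<path>.meta.json`` records communities, group column
        names and, for synthetic data, the generating spec and seed.
        """
        path = Path(path)
        table = self.scores.copy()
        group_cols: list[str] = []
        if self.groups is not None:
            for c in self.groups.columns:
                table[c] = self.groups[c].to_numpy()
                group_cols.append(c)
        table.to_csv(path, index=False)
        meta = {"communities": self.communities, "group_columns": group_cols}
        if ground_truth is not None:
            meta["ground_truth"] = ground_truth
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        communities: dict[str, str] | None = None,
        group_columns: list[str] | None = None,
    ) -> "QuestionnaireDataset":
        """Read a dataset written by :meth:`to_csv` (or any plain CSV).

        If a sidecar ``<path>.meta.json`` exists, communities and group
        columns default to its contents.
        """
        path = Path(path)
        table = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if communities is None:
                communities = meta.get("communities") or {}
            if group_columns is None:
                group_columns = meta.get("group_columns") or []
        communities = communities or {}
        group_columns = group_columns or []
        groups = table[group_columns].copy() if group_columns else None
        scores = table.drop(columns=group_columns)
        return cls(scores, communities, groups)
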