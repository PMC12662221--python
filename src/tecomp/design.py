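"""Experimental-design and accessibility-matrix containers.

A :class:`ConditionDesign` names the samples of an induction experiment and
assigns each a semantic role: the uninduced baseline, dose-sorted induced
fractions (low/high CEBPa) at one or more time points, and the two reference
cell states (ESC and TSC).  An :class:`AccessibilityMatrix` holds the
region x sample signal those samples produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

ROLES = ("baseline", "induced_low", "induced_high", "esc_ref", "tsc_ref")
INDUCED_ROLES = ("induced_low", "induced_high")


@dataclass(frozen=True)
class SampleInfo:
    sample: str        # column label in the matrix
    condition: str     # condition group (replicates share it)
    role: str          # one of ROLES
    time: str | None = None     # e.g. "48h", for induced conditions
    replicate: int = 1


class ConditionDesign:
    """Semantic roles of the samples in an accessibility experiment.

    Invariants: exactly one baseline condition, at least one induced_low and
    one induced_high condition, and exactly one esc_ref and one tsc_ref
    condition (each condition may have several replicates).
    """

    def __init__(self, samples: Iterable[SampleInfo]) -> None:
        self.samples = list(samples)
        if not self.samples:
            raise ValueError("design has no samples")
        for s in self.samples:
            if s.role not in ROLES:
                raise ValueError(f"unknown role {s.role!r} for sample {s.sample!r}")
        labels = [s.sample for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        by_role = self._conditions_by_role()
        for role in ("baseline", "esc_ref", "tsc_ref"):
            if len(by_role.get(role, [])) != 1:
                raise ValueError(f"design needs exactly one {role} condition")
        for role in INDUCED_ROLES:
            if not by_role.get(role):
                raise ValueError(f"design needs at least one {role} condition")

    def _conditions_by_role(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            lst = out.setdefault(s.role, [])
            if s.condition not in lst:
                lst.append(s.condition)
        return out

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def role_of(self, condition: str) -> str:
        for s in self.samples:
            if s.condition == condition:
                return s.role
        raise KeyError(condition)

    def time_of(self, condition: str) -> str | None:
        for s in self.samples:
            if s.condition == condition:
                return s.time
        raise KeyError(condition)

    def conditions_with_role(self, role: str) -> list[str]:
        return self._conditions_by_role().get(role, [])

    @property
    def baseline(self) -> str:
        return self.conditions_with_role("baseline")[0]

    @property
    def esc_ref(self) -> str:
        return self.conditions_with_role("esc_ref")[0]

    @property
    def tsc_ref(self) -> str:
        return self.conditions_with_role("tsc_ref")[0]

    @property
    def induced_conditions(self) -> list[str]:
        return [c for c in self.conditions if self.role_of(c) in INDUCED_ROLES]

    def samples_of(self, condition: str) -> list[str]:
        return [s.sample for s in self.samples if s.condition == condition]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "samples": [
                {
                    "sample": s.sample,
                    "condition": s.condition,
                    "role": s.role,
                    "time": s.time,
                    "replicate": s.replicate,
                }
                for s in self.samples
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConditionDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            SampleInfo(
                sample=str(d["sample"]),
                condition=str(d["condition"]),
                role=str(d["role"]),
                time=d.get("time"),
                replicate=int(d.get("replicate", 1)),
            )
            for d in payload["samples"]
        )


class AccessibilityMatrix:
    """Region x sample signal matrix (raw counts or normalized signal).

    Rows are region ids (``chrom:start-end`` or peak names), columns sample
    labels matching a :class:`ConditionDesign`.
    """

    def __init__(self, values: pd.DataFrame, normalized: bool = False) -> None:
        if values.index.duplicated().any():
            raise ValueError("region ids must be unique")
        if (values.to_numpy() < 0).any():
            raise ValueError("signal values must be non-negative")
        self.values = values
        self.normalized = normalized

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def cpm(self) -> "AccessibilityMatrix":
        """Per-million column normalization (each column sums to 1e6)."""
        libs = self.library_sizes()
        if (libs == 0).any():
            raise ValueError("zero library size column(s)")
        return AccessibilityMatrix(self.values / libs * 1e6, normalized=True)

    def condition_sum(self, design: ConditionDesign, condition: str) -> pd.Series:
        """Replicate-summed signal for one condition."""
        cols = design.samples_of(condition)
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise KeyError(f"samples missing from matrix: {missing}")
        return self.values[cols].sum(axis=1)

    def condition_mean(self, design: ConditionDesign, condition: str) -> pd.Series:
        cols = design.samples_of(condition)
        return self.values[cols].mean(axis=1)

    def restrict(self, region_ids: Iterable[str]) -> "AccessibilityMatrix":
        ids = list(region_ids)
        missing = [r for r in ids if r not in self.values.index]
        if missing:
            raise KeyError(f"regions missing from matrix: {missing[:5]}")
        return AccessibilityMatrix(self.values.loc[ids], normalized=self.normalized)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "AccessibilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, normalized=normalized)
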