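"""Experimental design: treatment groups, replication, and seed streams.

The default design mirrors a three-treatment plant stress experiment:
``M`` (photosynthetically active radiation control), ``N`` (UV-B
radiation) and ``Q`` (UV-B plus exogenous abscisic acid), each with
three biological replicates.  Contrasts are taken between consecutive
groups (``MvsN``: the UV-B effect; ``NvsQ``: the ABA effect on top of
UV-B), with fold changes expressed treatment-over-control.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GROUPS: tuple[str, ...] = ("M", "N", "Q")


def comparison_label(control: str, treatment: str) -> str:
    """Canonical label of a contrast, e.g. ``MvsN`` for N over M."""
    return f"{control}vs{treatment}"


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from one master seed.

    Every stochastic stage of the package draws from its own named
    stream so that adding a stage never perturbs the draws of another.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class StudyDesign:
    """Ordered treatment groups with equal replication.

    Parameters
    ----------
    groups:
        Ordered, unique group labels.  Order matters: contrasts are
        formed between consecutive groups.
    replicates_per_group:
        Biological replicates per group (at least 2).
    seed:
        Master seed for every generator attached to this design.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.replicates_per_group

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}{i}"
            for g in self.groups
            for i in range(1, self.replicates_per_group + 1)
        ]

    def samples_of(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [f"{group}{i}" for i in range(1, self.replicates_per_group + 1)]

    def group_map(self) -> pd.Series:
        """sample_id -> group, in design order."""
        return pd.Series(
            {s: g for g in self.groups for s in self.samples_of(g)},
            name="group",
        ).rename_axis("sample_id")

    def comparisons(self) -> list[tuple[str, str]]:
        """Consecutive (control, treatment) pairs."""
        return list(zip(self.groups[:-1], self.groups[1:]))

    def comparison_labels(self) -> list[str]:
        return [comparison_label(c, t) for c, t in self.comparisons()]
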