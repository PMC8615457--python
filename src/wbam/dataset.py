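"""Trial-level WBAM-range observations and pre/post pairing.

The statistical models relate each patient's post-rehabilitation WBAM
range to the pre-rehabilitation value of the *same trial index*, so the
trial-level dataset (patient, group AF/CT, phase pre/post, trial index,
range value) must be paired before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("AF", "CT")
PHASES = ("pre", "post")

RANGE_COLUMNS = ["patient_id", "group", "phase", "trial", "range_value"]
PAIR_COLUMNS = ["patient_id", "group", "trial", "pre_value", "post_value"]


class PairingError(ValueError):
    """A patient lacks pre or post trials."""


@dataclass(frozen=True)
class RangeObservation:
    """One trial's dimensionless WBAM range."""

    patient_id: str
    group: str
    phase: str
    trial_index: int
    range_value: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if not self.range_value >= 0:
            raise ValueError("range_value must be >= 0")


class RangeDataset:
    """Collection of :class:`RangeObservation` with uniqueness checks."""

    def __init__(self, observations: list[RangeObservation]):
        keys = [(o.patient_id, o.phase, o.trial_index) for o in observations]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (patient, phase, trial) observations: {dupes[:5]}")
        groups = {o.patient_id: o.group for o in observations}
        for o in observations:
            if groups[o.patient_id] != o.group:
                raise ValueError(f"patient {o.patient_id} appears in both groups")
        self.observations = list(observations)

    def __len__(self) -> int:
        return len(self.observations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (o.patient_id, o.group, o.phase, o.trial_index, o.range_value)
                for o in self.observations
            ],
            columns=RANGE_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RangeDataset":
        missing = set(RANGE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"range dataset missing columns: {sorted(missing)}")
        obs = [
            RangeObservation(
                patient_id=str(row.patient_id),
                group=str(row.group),
                phase=str(row.phase),
                trial_index=int(row.trial),
                range_value=float(row.range_value),
            )
            for row in frame.itertuples()
        ]
        return cls(obs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RangeDataset":
        return cls.from_frame(pd.read_csv(path))


def pair_trials(dataset: RangeDataset, mode: str = "index") -> pd.DataFrame:
    """Pair each patient's pre and post trials for model fitting.

    mode="index" (default): the i-th pre trial (ascending trial order) is
    paired with the i-th post trial; the longer list is truncated to the
    shorter, with a logged warning for dropped trials.
    mode="pre-mean": every post trial is paired against the patient's
    mean pre value.

    Returns a DataFrame with columns patient_id, group, trial, pre_value,
    post_value.
    """
    if mode not in ("index", "pre-mean"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    frame = dataset.to_frame()
    rows = []
    for patient_id, sub in frame.groupby("patient_id", sort=True):
        pre = sub[sub.phase == "pre"].sort_values("trial")
        post = sub[sub.phase == "post"].sort_values("trial")
        if pre.empty or post.empty:
            raise PairingError(f"patient {patient_id} lacks pre or post trials")
        group = sub.group.iloc[0]
        if mode == "index":
            n = min(len(pre), len(post))
            if len(pre) != len(post):
                logger.warning(
                    "patient %s: %d pre / %d post trials; pairing first %d of each",
                    patient_id, len(pre), len(post), n,
                )
            for k in range(n):
                rows.append(
                    (patient_id, group, int(post.trial.iloc[k]),
                     float(pre.range_value.iloc[k]), float(post.range_value.iloc[k]))
                )
        else:
            pre_mean = float(pre.range_value.mean())
            for row in post.itertuples():
                rows.append((patient_id, group, int(row.trial), pre_mean, float(row.range_value)))
    paired = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if not (paired.pre_value > 0).all():
        bad = paired[paired.pre_value <= 0].patient_id.unique()
        raise PairingError(f"non-positive pre values for patients {list(bad)}")
    paired["is_af"] = (paired.group == "AF").astype(float)
    return paired


def group_indicator(paired: pd.DataFrame) -> np.ndarray:
    """1.0 for AF-group pairs, 0.0 for CT (gates the feedback effect)."""
    return paired["is_af"].to_numpy(dtype=float)
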