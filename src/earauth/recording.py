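"""Core containers: a single labeled EEG recording and a corpus of them.

The montage is a three-electrode custom-fit earpiece per ear (concha,
canal-front, canal-back), plus Fp1 and a right-mastoid ring electrode.
All generated/loaded data are already referenced at the left mastoid, in
microvolts; the reference channel itself is never a data row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default channel order: left ear triplet, right ear triplet, scalp, mastoid.
CHANNEL_LABELS: tuple[str, ...] = (
    "L_concha",
    "L_front",
    "L_back",
    "R_concha",
    "R_front",
    "R_back",
    "Fp1",
    "R_mastoid",
)

EAR_CHANNELS: tuple[str, ...] = CHANNEL_LABELS[:6]


@dataclass
class ProtocolConfig:
    """Recording-session protocol: trials per task, trial length, rate.

    Defaults follow a 2 x 5-trial design with 10 s trials at 200 Hz, i.e.
    100 s of data per (subject, task).
    """

    n_trials: int = 10
    trial_duration_s: float = 10.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if self.fs < 100.0:
            raise ValueError("fs must be >= 100 Hz")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.fs))

    @property
    def seconds_per_task(self) -> float:
        return self.n_trials * self.trial_duration_s


@dataclass
class Recording:
    """One trial: a channels x samples matrix (µV) with identity labels."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str
    task_name: str
    trial_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.data.shape[0] == 0:
            raise ValueError("recording must contain at least one channel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the samples of one channel by label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None
        return self.data[i]


@dataclass
class Corpus:
    """A collection of recordings with a subject/task registry."""

    recordings: list[Recording] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.subject_id, None)
        return tuple(seen)

    @property
    def task_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.task_name, None)
        return tuple(seen)

    def select(self, subject_id: str | None = None, task_name: str | None = None) -> list[Recording]:
        """All recordings matching the given subject and/or task."""
        out = []
        for r in self.recordings:
            if subject_id is not None and r.subject_id != subject_id:
                continue
            if task_name is not None and r.task_name != task_name:
                continue
            out.append(r)
        return out

    def get(self, subject_id: str, task_name: str, trial_index: int) -> Recording:
        for r in self.recordings:
            if (
                r.subject_id == subject_id
                and r.task_name == task_name
                and r.trial_index == trial_index
            ):
                return r
        raise KeyError(f"no recording ({subject_id}, {task_name}, trial {trial_index})")
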