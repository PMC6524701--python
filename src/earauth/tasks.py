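"""The nine-task mental-task battery used for passthought authentication.

Each task is a short mental activity a wearer performs while EEG is
recorded from in-ear electrodes.  Tasks differ along four attributes that
matter for authentication: whether an external stimulus is delivered,
whether the wearer holds a personal secret (the knowledge factor), the
kind of mental imagery involved, and whether the eyes are open (which
modulates occipito-parietal alpha power).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TaskSpec:
    """One mental task and its authentication-relevant attributes."""

    name: str
    has_stimulus: bool
    has_secret: bool
    imagery: str  # one of {"none", "motor", "aural", "visual"}
    eyes_open: bool

    def __post_init__(self) -> None:
        if self.imagery not in {"none", "motor", "aural", "visual"}:
            raise ValueError(f"unknown imagery kind: {self.imagery!r}")


#: Canonical battery order; used for deterministic tie-breaking.
TASK_BATTERY: tuple[TaskSpec, ...] = (
    TaskSpec("breathe", has_stimulus=False, has_secret=False, imagery="none", eyes_open=False),
    TaskSpec("breathe-open", has_stimulus=False, has_secret=False, imagery="none", eyes_open=True),
    TaskSpec("sport", has_stimulus=False, has_secret=True, imagery="motor", eyes_open=False),
    TaskSpec("song", has_stimulus=False, has_secret=True, imagery="aural", eyes_open=False),
    TaskSpec("song-open", has_stimulus=False, has_secret=True, imagery="aural", eyes_open=True),
    TaskSpec("speech", has_stimulus=False, has_secret=True, imagery="aural", eyes_open=False),
    TaskSpec("listen", has_stimulus=True, has_secret=False, imagery="none", eyes_open=False),
    TaskSpec("face", has_stimulus=False, has_secret=True, imagery="visual", eyes_open=False),
    TaskSpec("sequence", has_stimulus=True, has_secret=True, imagery="visual", eyes_open=True),
)

TASK_NAMES: tuple[str, ...] = tuple(t.name for t in TASK_BATTERY)

_BY_NAME = {t.name: t for t in TASK_BATTERY}


def get_task(name: str) -> TaskSpec:
    """Look up a task in the battery by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown task {name!r}; battery: {', '.join(TASK_NAMES)}") from None


def task_order(name: str) -> int:
    """Position of ``name`` in the canonical battery (for tie-breaking)."""
    return TASK_NAMES.index(name)
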