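"""Data-quality checks: alpha attenuation and the >32 Hz EMG control.

Two validations that recorded (or generated) EEG must pass before the
authentication results can be trusted:

1. **Alpha attenuation** — 8-12 Hz band power during eyes-closed relaxed
   breathing should exceed that of the eyes-open variant of the same
   task, channel by channel.  This is the classic physiological check
   that electrodes are picking up cortical signal.
2. **EMG control** — after removing every spectral bin at or below
   32 Hz, the remaining (non-cortical, muscle-dominated) features should
   no longer support authentication: classifier error should sit near the
   chance level given by the test-set class proportions.  If it does not,
   the authenticator may be keying on muscle artifacts rather than EEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .authentication import assemble_training_set, train_authenticator
from .features import band_power, build_features, highpass_features, montage
from .recording import Corpus
from .tasks import TASK_NAMES

ALPHA_BAND = (8.0, 12.0)
EMG_CUTOFF_HZ = 32.0


@dataclass
class QcReport:
    """Results of the two quality checks."""

    alpha: pd.DataFrame | None = None        # subject x channel closed/open powers + ratio
    emg_control: pd.DataFrame | None = None  # per-(subject, task) error vs chance
    low_confidence: bool = False             # set when computed from a single trial

    def to_dict(self) -> dict:
        out: dict = {"low_confidence": self.low_confidence}
        if self.alpha is not None:
            out["alpha"] = self.alpha.to_dict(orient="records")
        if self.emg_control is not None:
            out["emg_control"] = self.emg_control.to_dict(orient="records")
        return out

    def summary(self) -> str:
        lines = []
        if self.alpha is not None:
            worst = self.alpha["ratio"].min()
            lines.append(
                f"alpha attenuation: {len(self.alpha)} subject-channel ratios, "
                f"min closed/open ratio {worst:.2f}"
            )
        if self.emg_control is not None:
            gap = (self.emg_control["error"] - self.emg_control["chance_error"]).abs().mean()
            lines.append(
                f">32 Hz control: mean |error - chance| = {gap:.3f} over "
                f"{len(self.emg_control)} classifiers"
            )
        if self.low_confidence:
            lines.append("WARNING: single-trial estimate, low confidence")
        return "\n".join(lines) if lines else "empty QC report"


def alpha_attenuation_check(
    corpus: Corpus,
    band: tuple[float, float] = ALPHA_BAND,
    channels: tuple[str, ...] | None = None,
    window_len: int = 100,
) -> QcReport:
    """Per-subject, per-channel alpha power closed vs open and their ratio.

    Compares the eyes-closed *breathe* task against *breathe-open*,
    averaging band power over all trials and windows.
    """
    rows = []
    single_trial = False
    for subject in corpus.subjects:
        closed = corpus.select(subject, "breathe")
        opened = corpus.select(subject, "breathe-open")
        if not closed or not opened:
            missing = "breathe" if not closed else "breathe-open"
            raise ValueError(f"subject {subject} lacks the {missing!r} task")
        single_trial |= len(closed) == 1 or len(opened) == 1
        labels = closed[0].channel_labels
        for lbl in labels:
            powers = {}
            for cond, recs in (("closed", closed), ("open", opened)):
                sub = Corpus(recordings=recs)
                fm = build_features(sub, montage(f"single:{lbl}"), window_len=window_len)
                powers[cond] = float(np.mean(band_power(fm, band)))
            ratio = powers["closed"] / powers["open"] if powers["open"] > 0 else np.nan
            rows.append(
                {
                    "subject": subject,
                    "channel": lbl,
                    "alpha_closed_uv2": powers["closed"],
                    "alpha_open_uv2": powers["open"],
                    "ratio": ratio,
                }
            )
    return QcReport(alpha=pd.DataFrame(rows), low_confidence=single_trial)


def chance_error(y_test: np.ndarray) -> float:
    """Base-rate error: what a majority-class predictor would score."""
    y_test = np.asarray(y_test)
    p_pos = float(np.mean(y_test == 1))
    return min(p_pos, 1.0 - p_pos)


def emg_control_analysis(
    corpus: Corpus,
    cutoff_hz: float = EMG_CUTOFF_HZ,
    montage_name: str = "left3",
    scheme: str = "default",
    params=None,
    seed: int = 0,
    neg_ratio: float = 10.0,
    window_len: int = 100,
) -> QcReport:
    """Re-run authentication on >``cutoff_hz`` features only.

    For every (subject, task), trains the usual authenticator on the
    high-passed feature matrix and reports its holdout error epsilon next
    to the chance error of the same test set.  With no discriminative
    structure above the cutoff, the two should agree closely.
    """
    fm = highpass_features(
        build_features(corpus, montage(montage_name), window_len=window_len), cutoff_hz
    )
    subjects = list(corpus.subjects)
    tasks = [t for t in TASK_NAMES if t in corpus.task_names]
    rows = []
    for s_i, subject in enumerate(subjects):
        for t_i, task in enumerate(tasks):
            cell_seed = (seed * 1_000_003 + s_i * 911 + t_i) % (2**31 - 1)
            ls = assemble_training_set(
                fm, subject, task, scheme=scheme, neg_ratio=neg_ratio, seed=cell_seed
            )
            clf = train_authenticator(ls, params=params, seed=cell_seed)
            pred = clf.scores(ls.X_test) > clf.threshold
            err = float(np.mean(pred != (ls.y_test > 0.5)))
            rows.append(
                {
                    "subject": subject,
                    "task": task,
                    "error": err,
                    "chance_error": chance_error(ls.y_test),
                }
            )
    return QcReport(emg_control=pd.DataFrame(rows))
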