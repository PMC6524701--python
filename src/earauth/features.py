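"""Windowed power-spectrum features for authentication.

Each trial is cut into consecutive non-overlapping 100-sample slices
(500 ms at 200 Hz).  For every slice and every electrode in the chosen
montage, a one-sided FFT power spectrum is computed (rectangular window,
no detrending, DC and Nyquist bins included) and the per-electrode
spectra are concatenated into one feature vector.  No dimensionality
reduction is applied.  Windows never straddle trial boundaries, so the
default protocol yields exactly 20 windows per 10 s trial and 200 windows
per (subject, task).

Power normalization: ``P_k = c_k |X_k|^2 / N`` with ``c_k = 2`` except at
DC and Nyquist, so that ``sum_k P_k`` equals the time-domain energy
``sum_t x_t^2`` (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording import CHANNEL_LABELS, Corpus, Recording

DEFAULT_WINDOW_LEN = 100

_MONTAGES: dict[str, tuple[str, ...]] = {
    "left3": ("L_concha", "L_front", "L_back"),
    "right3": ("R_concha", "R_front", "R_back"),
    "both6": ("L_concha", "L_front", "L_back", "R_concha", "R_front", "R_back"),
    "all": ("L_concha", "L_front", "L_back", "R_concha", "R_front", "R_back", "Fp1"),
    "fp1": ("Fp1",),
}


@dataclass(frozen=True)
class MontageSelection:
    """An ordered electrode subset used to build feature vectors."""

    name: str
    labels: tuple[str, ...]

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)


def montage(name: str, include_mastoid: bool = False) -> MontageSelection:
    """Resolve a montage by name.

    Named montages: ``left3``, ``right3``, ``both6``, ``all`` (both ears
    plus Fp1; the mastoid ring electrode is excluded unless
    ``include_mastoid``), ``fp1``, and ``single:<label>`` for any one
    channel, e.g. ``single:L_front``.
    """
    if name.startswith("single:"):
        label = name.split(":", 1)[1]
        if label not in CHANNEL_LABELS:
            raise KeyError(f"unknown channel {label!r} for single-electrode montage")
        return MontageSelection(name, (label,))
    try:
        labels = _MONTAGES[name]
    except KeyError:
        raise KeyError(
            f"unknown montage {name!r}; choose from {sorted(_MONTAGES)} or 'single:<label>'"
        ) from None
    if name == "all" and include_mastoid:
        labels = labels + ("R_mastoid",)
    return MontageSelection(name, labels)


@dataclass
class FeatureMatrix:
    """Windows x features matrix with per-window provenance labels.

    ``labels`` has one row per window with columns (subject, task, trial,
    window); ``values[i]`` is the concatenation, in montage order, of each
    electrode's one-sided power spectrum for that window.
    """

    values: np.ndarray
    labels: pd.DataFrame
    bin_hz: float
    n_bins_per_electrode: int
    montage: MontageSelection
    bin_freqs: np.ndarray  # center frequency of each per-electrode bin

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.labels):
            raise ValueError("values and labels disagree on the number of windows")
        expected = self.montage.n_electrodes * self.n_bins_per_electrode
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.values.shape[1]} features != "
                f"{self.montage.n_electrodes} electrodes x {self.n_bins_per_electrode} bins"
            )

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, subject: str | None = None, task: str | None = None) -> "FeatureMatrix":
        """Sub-matrix of windows matching a subject and/or task."""
        mask = np.ones(len(self.labels), dtype=bool)
        if subject is not None:
            mask &= (self.labels["subject"] == subject).to_numpy()
        if task is not None:
            mask &= (self.labels["task"] == task).to_numpy()
        return replace(
            self, values=self.values[mask], labels=self.labels.loc[mask].reset_index(drop=True)
        )

    def to_frame(self) -> pd.DataFrame:
        """Labels + feature columns as a single tidy DataFrame."""
        cols = [
            f"{lbl}_{f:g}Hz"
            for lbl in self.montage.labels
            for f in self.bin_freqs
        ]
        return pd.concat(
            [self.labels.reset_index(drop=True), pd.DataFrame(self.values, columns=cols)], axis=1
        )


def rereference(rec: Recording, new_ref_label: str) -> Recording:
    """Re-reference every channel to ``new_ref_label`` and drop it.

    The new reference channel's samples are subtracted from every channel;
    the (now identically zero) reference row is removed from the output.
    """
    if new_ref_label not in rec.channel_labels:
        raise KeyError(f"reference channel {new_ref_label!r} not present in recording")
    idx = rec.channel_labels.index(new_ref_label)
    ref = rec.data[idx]
    keep = [i for i in range(rec.n_channels) if i != idx]
    return Recording(
        data=rec.data[keep] - ref[None, :],
        fs=rec.fs,
        channel_labels=tuple(rec.channel_labels[i] for i in keep),
        subject_id=rec.subject_id,
        task_name=rec.task_name,
        trial_index=rec.trial_index,
    )


def slice_windows(rec: Recording, window_len: int = DEFAULT_WINDOW_LEN) -> list[np.ndarray]:
    """Cut a recording into consecutive non-overlapping windows.

    Returns floor(n_samples / window_len) arrays of shape
    (n_channels, window_len); trailing remainder samples are discarded.
    A recording shorter than one window yields an empty list.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    n_win = rec.n_samples // window_len
    return [
        rec.data[:, i * window_len : (i + 1) * window_len] for i in range(n_win)
    ]


def power_spectrum(window: np.ndarray, fs: float) -> np.ndarray:
    """One-sided FFT power spectrum of a 1-D window.

    Returns window_len // 2 + 1 non-negative values including the DC and
    Nyquist bins, normalized so the bins sum to the time-domain energy.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1:
        raise ValueError("power_spectrum expects a 1-D window")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    n = window.size
    spec = np.fft.rfft(window)
    power = np.abs(spec) ** 2 / n
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return power * scale


def spectrum_bin_freqs(window_len: int, fs: float) -> np.ndarray:
    """Center frequencies (Hz) of the one-sided spectrum bins."""
    return np.fft.rfftfreq(window_len, d=1.0 / fs)


def build_features(
    corpus: Corpus,
    montage_sel: MontageSelection,
    window_len: int = DEFAULT_WINDOW_LEN,
) -> FeatureMatrix:
    """Featurize a whole corpus under one electrode montage.

    Rows are ordered by (subject, task, trial, window) in corpus order;
    each row concatenates the selected electrodes' power spectra.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    n_bins = window_len // 2 + 1
    fs = corpus.recordings[0].fs
    rows: list[np.ndarray] = []
    label_rows: list[tuple[str, str, int, int]] = []
    for rec in corpus:
        for lbl in montage_sel.labels:
            if lbl not in rec.channel_labels:
                raise KeyError(
                    f"montage channel {lbl!r} missing from recording "
                    f"({rec.subject_id}, {rec.task_name}, trial {rec.trial_index})"
                )
        ch_idx = [rec.channel_labels.index(lbl) for lbl in montage_sel.labels]
        for w_i, win in enumerate(slice_windows(rec, window_len)):
            feats = np.concatenate(
                [power_spectrum(win[ci], rec.fs) for ci in ch_idx]
            )
            rows.append(feats)
            label_rows.append((rec.subject_id, rec.task_name, rec.trial_index, w_i))
    values = np.vstack(rows) if rows else np.empty((0, montage_sel.n_electrodes * n_bins))
    labels = pd.DataFrame(label_rows, columns=["subject", "task", "trial", "window"])
    return FeatureMatrix(
        values=values,
        labels=labels,
        bin_hz=fs / window_len,
        n_bins_per_electrode=n_bins,
        montage=montage_sel,
        bin_freqs=spectrum_bin_freqs(window_len, fs),
    )


def highpass_features(fm: FeatureMatrix, cutoff_hz: float = 32.0) -> FeatureMatrix:
    """Drop every spectral bin at or below ``cutoff_hz`` from each electrode.

    Used for the muscle-artifact control: with only >32 Hz (non-cortical)
    bins left, an authenticator should perform near chance if the
    discriminative signal is cortical.  Bins are removed, not zeroed.
    """
    nyquist = fm.bin_freqs[-1]
    keep = fm.bin_freqs > cutoff_hz
    if not np.any(keep):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz at or above Nyquist ({nyquist} Hz): no bins would remain"
        )
    n_el = fm.montage.n_electrodes
    col_mask = np.tile(keep, n_el)
    return FeatureMatrix(
        values=fm.values[:, col_mask],
        labels=fm.labels.copy(),
        bin_hz=fm.bin_hz,
        n_bins_per_electrode=int(keep.sum()),
        montage=fm.montage,
        bin_freqs=fm.bin_freqs[keep],
    )


def band_power(fm: FeatureMatrix, band: tuple[float, float]) -> np.ndarray:
    """Per-window total power in a frequency band, summed over electrodes.

    Band is inclusive of both edges on bin centers.
    """
    lo, hi = band
    in_band = (fm.bin_freqs >= lo) & (fm.bin_freqs <= hi)
    col_mask = np.tile(in_band, fm.montage.n_electrodes)
    return fm.values[:, col_mask].sum(axis=1)
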