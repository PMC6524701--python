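"""Authentication error metrics and evaluation protocols.

Definitions (counts over one test set):

* epsilon = E_W / E — plain binary error over E evaluated instances;
* FAR = FA_S / FA — fraction of the FA imposter (false) attempts that
  were wrongly accepted (FA_S successes);
* FRR = TA_U / TA — fraction of the TA genuine (true) attempts that were
  wrongly rejected (TA_U failures);
* HTER = (FAR + FRR) / 2, and ACC = 100 x (1 - HTER) on the percent
  scale.

On top of these, this module runs the full evaluation grid over
(subject, task, montage, scheme), selects each subject's best task,
performs the leave-one-out robustness protocol, and compares the four
negative-example training schemes.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .authentication import (
    AuthClassifier,
    LabeledSet,
    assemble_training_set,
    predict,
    train_authenticator,
)
from .features import FeatureMatrix, MontageSelection, build_features, montage
from .recording import Corpus
from .tasks import TASK_NAMES, task_order


@dataclass(frozen=True)
class EvalReport:
    """Attempt counts and error rates for one classifier (or aggregate)."""

    FA: int       # false (imposter) attempts
    FA_S: int     # successful false attempts
    TA: int       # true (genuine) attempts
    TA_U: int     # unsuccessful true attempts

    @property
    def E(self) -> int:
        return self.FA + self.TA

    @property
    def E_W(self) -> int:
        return self.FA_S + self.TA_U

    @property
    def epsilon(self) -> float:
        return self.E_W / self.E

    @property
    def FAR(self) -> float:
        return self.FA_S / self.FA

    @property
    def FRR(self) -> float:
        return self.TA_U / self.TA

    @property
    def HTER(self) -> float:
        return (self.FAR + self.FRR) / 2.0

    @property
    def ACC(self) -> float:
        return 100.0 * (1.0 - self.HTER)


def compute_rates(FA: int, FA_S: int, TA: int, TA_U: int) -> EvalReport:
    """Validate attempt counts and wrap them in an EvalReport."""
    if FA <= 0 or TA <= 0:
        raise ValueError("FA and TA must be positive: rates undefined otherwise")
    if not 0 <= FA_S <= FA:
        raise ValueError("need 0 <= FA_S <= FA")
    if not 0 <= TA_U <= TA:
        raise ValueError("need 0 <= TA_U <= TA")
    return EvalReport(FA=int(FA), FA_S=int(FA_S), TA=int(TA), TA_U=int(TA_U))


def compute_accuracy(FAR: float, FRR: float) -> tuple[float, float]:
    """(HTER, ACC) from a FAR/FRR pair; ACC is on the percent scale."""
    if not (0 <= FAR <= 1 and 0 <= FRR <= 1):
        raise ValueError("FAR and FRR must lie in [0, 1]")
    hter = (FAR + FRR) / 2.0
    return hter, 100.0 * (1.0 - hter)


def evaluate_classifier(clf: AuthClassifier, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Score a labeled test set and count acceptance/rejection errors.

    Negative-labeled rows are imposter attempts (FA), positive-labeled
    rows genuine attempts (TA).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("test set must contain both classes")
    decisions, _ = predict(clf, X)
    neg = y == 0
    pos = ~neg
    return EvalReport(
        FA=int(neg.sum()),
        FA_S=int(np.sum(decisions[neg])),
        TA=int(pos.sum()),
        TA_U=int(np.sum(~decisions[pos])),
    )


def aggregate_mean(values) -> float:
    """Arithmetic mean of per-participant rates."""
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty list of rates")
    if any(not 0 <= v <= 1 for v in values):
        raise ValueError("rates must lie in [0, 1]")
    return float(np.mean(values))


def round_rate(value: float, decimals: int = 5) -> float:
    """Round half away from zero, as in printed result tables."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _fit_and_eval(
    fm: FeatureMatrix,
    subject: str,
    task: str,
    scheme: str,
    neg_ratio: float,
    params,
    seed: int,
    split_by: str = "trial",
    exclude_subjects=(),
) -> EvalReport:
    ls = assemble_training_set(
        fm,
        subject,
        task,
        scheme=scheme,
        neg_ratio=neg_ratio,
        seed=seed,
        split_by=split_by,
        exclude_subjects=exclude_subjects,
    )
    clf = train_authenticator(ls, params=params, seed=seed)
    return evaluate_classifier(clf, ls.X_test, ls.y_test)


def run_full_grid(
    corpus: Corpus,
    montages=("left3",),
    schemes=("default",),
    params=None,
    seed: int = 0,
    neg_ratio: float = 10.0,
    window_len: int = 100,
    split_by: str = "trial",
) -> pd.DataFrame:
    """One EvalReport per (subject, task, montage, scheme), as a tidy table.

    Columns: subject, task, montage, scheme, the four attempt counts, and
    FAR/FRR/HTER/ACC.  Deterministic per master seed: each cell's
    sampling/training seed is derived from (seed, subject, task, montage,
    scheme) so results do not depend on iteration order.
    """
    subjects = list(corpus.subjects)
    if len(subjects) < 2:
        raise ValueError("grid evaluation needs at least two subjects")
    tasks = [t for t in TASK_NAMES if t in corpus.task_names]
    rows = []
    for m_i, m_name in enumerate(montages):
        sel = montage(m_name) if isinstance(m_name, str) else m_name
        fm = build_features(corpus, sel, window_len=window_len)
        for sch_i, scheme in enumerate(schemes):
            for s_i, subject in enumerate(subjects):
                for t_i, task in enumerate(tasks):
                    cell_seed = (
                        seed * 1_000_003 + m_i * 97_001 + sch_i * 9_103 + s_i * 911 + t_i
                    ) % (2**31 - 1)
                    rep = _fit_and_eval(
                        fm, subject, task, scheme, neg_ratio, params, cell_seed,
                        split_by=split_by,
                    )
                    rows.append(
                        {
                            "subject": subject,
                            "task": task,
                            "montage": sel.name,
                            "scheme": scheme,
                            "FA": rep.FA,
                            "FA_S": rep.FA_S,
                            "TA": rep.TA,
                            "TA_U": rep.TA_U,
                            "FAR": rep.FAR,
                            "FRR": rep.FRR,
                            "HTER": rep.HTER,
                            "ACC": rep.ACC,
                        }
                    )
    return pd.DataFrame(rows)


def rate_table(grid: pd.DataFrame, rate: str = "FAR") -> pd.DataFrame:
    """Task x subject matrix of one rate, with a Mean column (5 decimals)."""
    sub = grid.pivot_table(index="task", columns="subject", values=rate, aggfunc="first")
    sub = sub.sort_index()  # alphabetical task rows, as results tables print them
    sub["Mean"] = [round_rate(aggregate_mean(row.to_numpy())) for _, row in sub.iterrows()]
    return sub


def montage_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-montage mean FAR/FRR with standard errors across subjects."""
    rows = []
    for m_name, g in grid.groupby("montage"):
        per_subject = g.groupby("subject")[["FAR", "FRR"]].mean()
        n = len(per_subject)
        rows.append(
            {
                "montage": m_name,
                "FAR_mean": per_subject["FAR"].mean(),
                "FAR_se": per_subject["FAR"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "FRR_mean": per_subject["FRR"].mean(),
                "FRR_se": per_subject["FRR"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def select_best_tasks(grid: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-subject best task and the headline accuracy.

    The best task minimizes FAR, breaking ties by lower FRR and then by
    battery order.  The headline is computed from the mean best-task FAR
    and the mean of their associated FRRs via HTER.
    """
    if grid["montage"].nunique() != 1 or grid["scheme"].nunique() != 1:
        raise ValueError("best-task selection expects a single montage and scheme")
    subjects = grid["subject"].unique()
    tasks_present = set(grid["task"])
    rows = []
    for subject in subjects:
        g = grid[grid["subject"] == subject]
        if set(g["task"]) != tasks_present:
            raise ValueError(f"incomplete grid for subject {subject}")
        g = g.assign(order=[task_order(t) for t in g["task"]])
        best = g.sort_values(["FAR", "FRR", "order"]).iloc[0]
        rows.append(
            {"subject": subject, "task": best["task"], "FAR": best["FAR"], "FRR": best["FRR"]}
        )
    best_df = pd.DataFrame(rows)
    far_mean = aggregate_mean(best_df["FAR"])
    frr_mean = aggregate_mean(best_df["FRR"])
    hter, acc = compute_accuracy(far_mean, frr_mean)
    headline = {"FAR_mean": far_mean, "FRR_mean": frr_mean, "HTER": hter, "ACC": acc}
    return best_df, headline


def leave_one_out_far(
    corpus: Corpus,
    subject: str,
    task: str,
    fm: FeatureMatrix | None = None,
    scheme: str = "default",
    params=None,
    seed: int = 0,
    neg_ratio: float = 10.0,
    montage_name: str = "left3",
) -> list[float]:
    """FAR of one target, re-trained once with each other subject left out.

    With n subjects the result has n - 1 entries: the classifier for
    (subject, task) is retrained with one other subject removed from the
    negative pool each time and its holdout FAR recorded.
    """
    subjects = list(corpus.subjects)
    if len(subjects) < 3:
        raise ValueError("leave-one-out needs at least three subjects")
    if subject not in subjects:
        raise ValueError(f"unknown target subject {subject!r}")
    if fm is None:
        fm = build_features(corpus, montage(montage_name))
    fars = []
    for o_i, other in enumerate(s for s in subjects if s != subject):
        cell_seed = (seed * 1_000_003 + o_i) % (2**31 - 1)
        rep = _fit_and_eval(
            fm, subject, task, scheme, neg_ratio, params, cell_seed,
            exclude_subjects=(other,),
        )
        fars.append(rep.FAR)
    return fars


def factor_analysis(
    corpus: Corpus,
    params=None,
    seed: int = 0,
    neg_ratio: float = 10.0,
    montage_name: str = "left3",
    schemes=("default", "inherence_only", "knowledge_only", "combined"),
) -> pd.DataFrame:
    """Mean FAR/FRR across all (subject, task) pairs for each scheme.

    Reproduces the factor-contribution comparison: the default scheme
    engages both inherence and knowledge factors; the other rows isolate
    them.  Rows appear in the canonical scheme order.
    """
    grid = run_full_grid(
        corpus,
        montages=(montage_name,),
        schemes=schemes,
        params=params,
        seed=seed,
        neg_ratio=neg_ratio,
    )
    rows = []
    from .authentication import SCHEME_RULES

    for scheme in schemes:
        g = grid[grid["scheme"] == scheme]
        rows.append(
            {
                "scheme": scheme,
                "positives": SCHEME_RULES[scheme][0],
                "negatives": SCHEME_RULES[scheme][1],
                "FAR": aggregate_mean(g["FAR"]),
                "FRR": aggregate_mean(g["FRR"]),
            }
        )
    return pd.DataFrame(rows)
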