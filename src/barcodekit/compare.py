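"""Classifier comparison with the corrected resampled paired t-test.

The correction is the Nadeau-Bengio variance inflation: with per-run score
differences d_i over n = folds * repeats runs sharing one fold schedule,

    t = mean(d) / sqrt((1/n + n2/n1) * var(d)),   df = n - 1,

where n2/n1 is the test/train size ratio (1/9 for 10-fold CV) and var is the
unbiased sample variance.  At ratio 0 the statistic reduces exactly to the
classic paired t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class PairedRuns:
    scores_a: np.ndarray
    scores_b: np.ndarray
    test_train_ratio: float

    def __post_init__(self):
        self.scores_a = np.asarray(self.scores_a, dtype=float)
        self.scores_b = np.asarray(self.scores_b, dtype=float)
        if self.scores_a.shape != self.scores_b.shape or self.scores_a.ndim != 1:
            raise DataError("paired runs require equal-length 1-D score lists")
        if self.scores_a.size < 2:
            raise DataError("paired t-test needs at least 2 runs")
        if self.test_train_ratio < 0:
            raise DataError("test/train ratio must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    significant: bool
    degenerate: bool = False


def corrected_ttest(pr: PairedRuns, alpha: float = 0.05) -> TTestResult:
    """Corrected resampled paired t-test, two-tailed at ``alpha``.

    Degenerate cases: zero variance with zero mean difference gives t = 0
    (not significant); zero variance with a non-zero mean difference is
    flagged degenerate ("infinite t") and reported significant.
    """
    d = pr.scores_a - pr.scores_b
    n = d.size
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    df = n - 1
    if var == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p_value=1.0, significant=False)
        return TTestResult(
            t=math.copysign(math.inf, mean),
            df=df,
            p_value=0.0,
            significant=True,
            degenerate=True,
        )
    t = mean / math.sqrt((1.0 / n + pr.test_train_ratio) * var)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p_value=p, significant=p < alpha)


def rank_classifiers(
    all_runs: dict[str, list[float]],
    baseline: str,
    test_train_ratio: float = 1.0 / 9.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean +/- SD per classifier plus pairwise significance vs the baseline.

    Rows are stably sorted by mean score, descending (input order preserved
    among ties).  The ``mark`` column records win/tie/loss against the
    baseline at the two-tailed ``alpha`` level.
    """
    if baseline not in all_runs:
        raise DataError(f"baseline {baseline!r} not among classifiers")
    base_scores = np.asarray(all_runs[baseline], dtype=float)
    rows = []
    for name, scores in all_runs.items():
        scores = np.asarray(scores, dtype=float)
        row = {
            "classifier": name,
            "mean": float(scores.mean()),
            "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
        }
        if name == baseline:
            row.update(t=float("nan"), p_value=float("nan"), significant=False, mark="baseline")
        else:
            res = corrected_ttest(
                PairedRuns(scores, base_scores, test_train_ratio), alpha=alpha
            )
            if not res.significant:
                mark = "tie"
            elif row["mean"] > base_scores.mean():
                mark = "win"
            else:
                mark = "loss"
            row.update(t=res.t, p_value=res.p_value, significant=res.significant, mark=mark)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("classifier")
    return df.sort_values("mean", ascending=False, kind="stable")
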