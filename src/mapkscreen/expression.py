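"""qPCR differential-expression calls.

Transcript levels are expressed as log2 ratios to GFP-dsRNA-treated
controls; a knockdown-like call requires both a mean log2 ratio below a
threshold (default -0.75) and an unpaired two-tailed Student's t-test
p-value below a significance cutoff (default 1e-4), the joint rule used
for calling pathway-component transcript depletion.  Raw p-values are
reported; Benjamini-Hochberg adjustment is available behind a flag but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class ExpressionCall:
    log2fc: float
    t_statistic: float
    p_value: float
    knockdown: bool


def expression_call(
    treated_reps,
    control_reps,
    log2_threshold: float = -0.75,
    p_threshold: float = 1e-4,
) -> ExpressionCall:
    """Differential call from log2-scale replicate quantities.

    Parameters
    ----------
    treated_reps, control_reps : >= 2 log2-scale replicate values each.
    log2_threshold : call threshold on the mean difference (negative for
        knockdown calls).
    p_threshold : two-tailed t-test significance cutoff in (0, 1).

    Returns
    -------
    ExpressionCall with ``log2fc = mean(treated) - mean(control)``,
    the Student (pooled-variance) t statistic and p-value, and the
    knockdown verdict (log2fc below threshold AND p below cutoff).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    treated = np.asarray(treated_reps, dtype=float)
    control = np.asarray(control_reps, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 replicates per group")
    log2fc = float(treated.mean() - control.mean())
    t, p = stats.ttest_ind(treated, control, equal_var=True)
    knockdown = (log2fc < log2_threshold) and (p < p_threshold)
    return ExpressionCall(log2fc, float(t), float(p), bool(knockdown))


class ExpressionCaller(BaseEstimator):
    """qPCR log2-ratio differential caller over a replicate table.

    Parameters
    ----------
    log2_threshold : mean log2-ratio call threshold (default -0.75).
    p_threshold : t-test p-value cutoff (default 1e-4).
    fdr : when True, apply Benjamini-Hochberg adjustment across the table
        and test the adjusted p-values against ``p_threshold``.
    """

    def __init__(
        self,
        log2_threshold: float = -0.75,
        p_threshold: float = 1e-4,
        fdr: bool = False,
    ):
        self.log2_threshold = log2_threshold
        self.p_threshold = p_threshold
        self.fdr = fdr

    def fit(self, X=None, y=None):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        self.n_features_in_ = 0 if X is None else np.shape(X)[-1]
        return self

    def call_table(self, replicates: pd.DataFrame) -> pd.DataFrame:
        """Call every row of a long replicate table.

        ``replicates`` needs columns ``unit`` (e.g. dsRNA x target
        transcript), ``group`` in {"treated", "control"}, and ``value``
        (log2 quantity).  Returns one row per unit with log2fc, t, p,
        (p_adj when ``fdr``), and the knockdown verdict.
        """
        check_is_fitted(self, "n_features_in_")
        required = {"unit", "group", "value"}
        missing = required - set(replicates.columns)
        if missing:
            raise ValueError(f"replicate table missing column(s): {sorted(missing)}")
        rows = []
        for unit, grp in replicates.groupby("unit", sort=True):
            treated = grp.loc[grp["group"] == "treated", "value"].to_numpy()
            control = grp.loc[grp["group"] == "control", "value"].to_numpy()
            c = expression_call(
                treated, control, log2_threshold=self.log2_threshold, p_threshold=1 - 1e-12
            )
            rows.append({"unit": unit, "log2fc": c.log2fc, "t": c.t_statistic, "p": c.p_value})
        out = pd.DataFrame(rows)
        p_eff = out["p"].to_numpy()
        if self.fdr:
            out["p_adj"] = stats.false_discovery_control(p_eff, method="bh")
            p_eff = out["p_adj"].to_numpy()
        out["knockdown"] = (out["log2fc"] < self.log2_threshold) & (p_eff < self.p_threshold)
        return out

    def predict(self, replicates: pd.DataFrame) -> np.ndarray:
        """Boolean knockdown verdict per unit."""
        return self.call_table(replicates)["knockdown"].to_numpy()
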