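"""Primary hit calling and promoter-system false-positive filtering.

A reagent is a primary hit when its normalized pMAPK value falls outside
the cutoff margins in the same direction in both the primary and the
confirmation screen (reproducibility rule).  Because pathway activation is
driven from a metallothionein (pMet) promoter, a reagent can score by
perturbing the expression system rather than the pathway; the promoter
filter removes reagents whose effect in the pMet reporter screens is large
enough, relative to their pMAPK effect, to explain the hit:

    fail  iff  |reporter| >= intercept + slope * |pMAPK|

a linear reconstruction of a signal-dependent cutoff, with both parameters
exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def promoter_filter(
    pmapk_value,
    reporter_value,
    slope: float = 0.5,
    intercept: float = 0.3,
) -> np.ndarray | bool:
    """Promoter-system false-positive test; True = pass (keep the hit).

    Vectorized over inputs.  A reagent fails when its absolute reporter
    effect reaches ``intercept + slope * |pMAPK|``.
    """
    pmapk = np.asarray(pmapk_value, dtype=float)
    reporter = np.asarray(reporter_value, dtype=float)
    passed = np.abs(reporter) < intercept + slope * np.abs(pmapk)
    return bool(passed) if passed.ndim == 0 else passed


def call_primary_hits(
    values: pd.DataFrame,
    up_cutoff: float = 0.3,
    down_cutoff: float = -0.3,
    require_confirmation: bool = True,
) -> pd.DataFrame:
    """Call primary hits from (confirmed) normalized pMAPK values.

    Parameters
    ----------
    values : one row per reagent with column ``value_primary`` and, when
        ``require_confirmation``, ``value_confirmation``.
    up_cutoff, down_cutoff : log-scale margins, ``down_cutoff < 0 <
        up_cutoff``.  Up hits (signal increase on knockdown) are negative-
        regulator candidates; down hits positive-regulator candidates.

    Returns
    -------
    Copy of ``values`` with boolean ``is_hit`` and ``direction`` in
    {"up", "down", ""} appended.
    """
    if not (down_cutoff < 0.0 < up_cutoff):
        raise ValueError(f"need down_cutoff < 0 < up_cutoff, got {down_cutoff}, {up_cutoff}")
    if "value_primary" not in values.columns:
        raise ValueError("values must have a 'value_primary' column")
    primary = values["value_primary"].to_numpy(dtype=float)
    if require_confirmation:
        if "value_confirmation" not in values.columns:
            raise ValueError("confirmation values required but 'value_confirmation' missing")
        conf = values["value_confirmation"].to_numpy(dtype=float)
    else:
        conf = primary
    up = (primary > up_cutoff) & (conf > up_cutoff)
    down = (primary < down_cutoff) & (conf < down_cutoff)
    out = values.copy()
    out["is_hit"] = up | down
    out["direction"] = np.where(up, "up", np.where(down, "down", ""))
    return out


class HitCaller(BaseEstimator):
    """Two-stage hit caller with promoter false-positive filtering.

    Parameters
    ----------
    up_cutoff, down_cutoff : primary-screen margins on the log10 scale.
    require_confirmation : demand the same-direction call in a second,
        independently screened value (reproducibility; also stands in for
        the non-overlapping-dsRNA off-target confirmation).
    promoter_slope, promoter_intercept : parameters of the reporter-vs-
        pMAPK linear cutoff.
    """

    def __init__(
        self,
        up_cutoff: float = 0.3,
        down_cutoff: float = -0.3,
        require_confirmation: bool = True,
        promoter_slope: float = 0.5,
        promoter_intercept: float = 0.3,
    ):
        self.up_cutoff = up_cutoff
        self.down_cutoff = down_cutoff
        self.require_confirmation = require_confirmation
        self.promoter_slope = promoter_slope
        self.promoter_intercept = promoter_intercept

    def fit(self, X: pd.DataFrame, y=None):
        if not (self.down_cutoff < 0.0 < self.up_cutoff):
            raise ValueError("need down_cutoff < 0 < up_cutoff")
        self.n_features_in_ = X.shape[1]
        return self

    def call(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full hit table: ``is_hit``, ``direction``, and when reporter
        columns are present ``promoter_pass`` plus the net ``validated``
        flag (hit that survives the promoter filter)."""
        check_is_fitted(self, "n_features_in_")
        out = call_primary_hits(
            X,
            up_cutoff=self.up_cutoff,
            down_cutoff=self.down_cutoff,
            require_confirmation=self.require_confirmation,
        )
        reporter_cols = [c for c in X.columns if c.startswith("reporter")]
        if reporter_cols:
            passed = np.ones(len(out), dtype=bool)
            for col in reporter_cols:
                passed &= promoter_filter(
                    out["value_primary"],
                    out[col],
                    slope=self.promoter_slope,
                    intercept=self.promoter_intercept,
                )
            out["promoter_pass"] = passed
            out["validated"] = out["is_hit"] & passed
        else:
            out["validated"] = out["is_hit"]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean validated-hit flag per reagent."""
        return self.call(X)["validated"].to_numpy()
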