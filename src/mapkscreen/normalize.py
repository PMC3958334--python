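"""Plate normalization, replicate aggregation, and Z'-factor QC.

Every screening plate carries GFP-dsRNA negative-control wells; sample
signals are expressed as the log ratio to the center of those in-plate
controls, which removes per-plate multiplicative bias (dilution, staining,
exposure).  Epistasis-screen values use log10; expression-type summaries
use log2.  Assay robustness is summarized by the Z'-factor,

    Z' = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|,

with Z' > 0.5 the conventional robust-assay threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

WELL_KEYS = ["plate", "well", "reagent_id", "role", "assay", "signal"]


@dataclass(frozen=True)
class QCStats:
    """Z'-factor statistics for one assay's control populations."""

    assay: str
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    zprime: float  # NaN when undefined (equal means)
    robust: bool
    undefined: bool = False


def zprime(pos_values, neg_values, assay: str = "", robust_threshold: float = 0.5) -> QCStats:
    """Z'-factor of a positive vs negative control population.

    Uses sample (n-1) standard deviations.  When the group means coincide
    the statistic is undefined; the result is flagged rather than returned
    as -inf.

    Parameters
    ----------
    pos_values, neg_values : array-like, at least 2 values each.
    robust_threshold : Z' above which the assay is flagged robust.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        return QCStats(assay, mu_p, sd_p, mu_n, sd_n, float("nan"), False, undefined=True)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return QCStats(assay, mu_p, sd_p, mu_n, sd_n, float(z), bool(z > robust_threshold))


def _control_center(signals: np.ndarray, method: str) -> float:
    if method == "median":
        return float(np.median(signals))
    if method == "geometric":
        return float(gmean(signals))
    raise ValueError(f"unknown center method {method!r}")


def normalize_plate(
    wells: pd.DataFrame,
    base: float = 10.0,
    center: str = "median",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Normalize one plate/assay of wells to its negative controls.

    Each well's value becomes ``log_base(signal / center(neg_ctrl
    signals))``; control wells are emitted too (centered near zero).

    Parameters
    ----------
    wells : rows of a single plate and assay, columns including
        ``plate, well, reagent_id, role, signal``.
    base : log base (10 for the pMAPK epistasis screens, 2 for
        expression-type ratios).
    center : "median" (robust to one contaminated control well) or
        "geometric" (makes the control mean exactly zero).
    pseudocount : added to every signal before the ratio when given;
        by default nonpositive signals are rejected (dropped and counted
        in ``frame.attrs["n_rejected"]``).

    Raises
    ------
    ValueError
        If the plate carries no negative-control well, or the control
        center is nonpositive.
    """
    plates = wells["plate"].unique()
    if len(plates) != 1:
        raise ValueError(f"normalize_plate expects a single plate, got {list(plates)}")
    plate = plates[0]
    wells = wells.copy()
    if pseudocount is not None:
        wells["signal"] = wells["signal"] + pseudocount
    bad = wells["signal"] <= 0
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("plate %s: dropping %d nonpositive-signal well(s)", plate, n_rejected)
        wells = wells[~bad]
    neg = wells.loc[wells["role"] == "neg_ctrl", "signal"].to_numpy()
    if neg.size == 0:
        raise ValueError(f"plate {plate!r} has no negative-control well")
    c = _control_center(neg, center)
    if c <= 0:
        raise ValueError(f"plate {plate!r}: nonpositive control center {c}")
    out = wells.copy()
    out["value"] = np.log(out["signal"].to_numpy() / c) / np.log(base)
    out.attrs["n_rejected"] = n_rejected
    return out


def aggregate_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Average replicate log-values per reagent and assay.

    Returns one row per (reagent_id, assay) with the replicate mean as
    ``value``, the sample sd as ``dispersion`` (NaN and flagged when only
    one replicate exists), and ``n_replicates``.
    """
    grouped = values.groupby(["reagent_id", "assay"], sort=True)["value"]
    out = grouped.agg(value="mean", dispersion=lambda v: v.std(ddof=1), n_replicates="size")
    out = out.reset_index()
    out["single_replicate"] = out["n_replicates"] == 1
    return out


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Transform raw well tables into normalized log-ratio values.

    Applies :func:`normalize_plate` per (assay, plate) group, choosing the
    log base per assay from ``base_map`` (default log10).

    Parameters
    ----------
    base_map : mapping assay -> log base; assays not listed use
        ``default_base``.
    default_base : default 10.0.
    center : control-center estimator, "median" or "geometric".
    pseudocount : optional pseudocount for zero signals; default None
        (reject such wells with a warning count).
    """

    def __init__(
        self,
        base_map: dict[str, float] | None = None,
        default_base: float = 10.0,
        center: str = "median",
        pseudocount: float | None = None,
    ):
        self.base_map = base_map
        self.default_base = default_base
        self.center = center
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in WELL_KEYS if c not in X.columns]
        if missing:
            raise ValueError(f"well table missing column(s): {missing}")
        self.assays_ = tuple(sorted(X["assay"].unique()))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-well normalized values with a ``value`` column appended."""
        check_is_fitted(self, "assays_")
        base_map = self.base_map or {}
        parts = []
        n_rejected = 0
        for (assay, _plate), grp in X.groupby(["assay", "plate"], sort=True):
            base = base_map.get(assay, self.default_base)
            norm = normalize_plate(
                grp, base=base, center=self.center, pseudocount=self.pseudocount
            )
            n_rejected += norm.attrs.get("n_rejected", 0)
            parts.append(norm)
        out = pd.concat(parts, ignore_index=True)
        out.attrs["n_rejected"] = n_rejected
        return out

    def qc(self, normalized: pd.DataFrame, robust_threshold: float = 0.5) -> pd.DataFrame:
        """Z'-factor per assay for both positive-control reagents.

        Computed on normalized values, negative controls vs each of the
        pos_ctrl_down / pos_ctrl_up populations.
        """
        rows = []
        for assay, grp in normalized.groupby("assay", sort=True):
            neg = grp.loc[grp["role"] == "neg_ctrl", "value"]
            for role in ("pos_ctrl_down", "pos_ctrl_up"):
                pos = grp.loc[grp["role"] == role, "value"]
                if len(pos) < 2 or len(neg) < 2:
                    continue
                stats = zprime(pos, neg, assay=assay, robust_threshold=robust_threshold)
                rows.append({"role": role, **stats.__dict__})
        return pd.DataFrame(rows)
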