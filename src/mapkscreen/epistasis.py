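"""Epistasis-interval assignment for RAS/MAPK screen candidates.

A gene knocked down in a panel of pathway-activation assays leaves a
six-value footprint: how strongly it suppresses (or boosts) pMAPK when the
pathway is driven at RAS, at RAF, or at MEK.  A regulator acting between
RAS and RAF can only modulate the RAS-driven assay; one acting between MEK
and MAPK modulates all six.  Each gene's log-transformed normalized profile
is therefore compared against three idealized interval profiles with a
weighted uncentered (cosine-type) Pearson correlation,

    r = sum_i(w_i x_i y_i) / sqrt(sum_i(w_i x_i^2) * sum_i(w_i y_i^2))

and assigned to the interval whose profile correlates most strongly in
magnitude.  The sign of r encodes regulator direction: depletion of a
positive regulator lowers pMAPK, giving negative profile values and hence
negative r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

#: Assay order of the epistasis panel. The weight vector is meaningful only
#: in this order, so profile inputs are validated by name against it.
EPISTASIS_ASSAYS: tuple[str, ...] = (
    "RASV12",
    "RAFED",
    "RAFCT",
    "RAFEDCT",
    "MEKEE",
    "MEKEE_PTPERi",
)

#: Default per-assay weights (RAS-driven assay counts triple, the
#: MEK+PTP-ER-RNAi assay double).
DEFAULT_WEIGHTS: tuple[float, ...] = (3.0, 1.0, 1.0, 1.0, 1.0, 2.0)

#: The three epistasis intervals of the RAS->RAF->MEK->MAPK cascade.
INTERVALS: tuple[str, ...] = ("RAS-RAF", "RAF-MEK", "MEK-MAPK")

#: Idealized profile of a negative regulator acting in each interval:
#: its depletion raises pMAPK only in assays driven at or upstream of the
#: interval where it acts.
IDEAL_PROFILES: dict[str, tuple[float, ...]] = {
    "RAS-RAF": (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "RAF-MEK": (1.0, 1.0, 1.0, 1.0, 0.0, 0.0),
    "MEK-MAPK": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
}

UNASSIGNED = "?"


class ZeroNormError(ValueError):
    """A profile has zero norm under the weights; r is undefined (not 0)."""


def ideal_profile(interval: str) -> np.ndarray:
    """Return the idealized six-assay profile for an epistasis interval.

    Parameters
    ----------
    interval : {"RAS-RAF", "RAF-MEK", "MEK-MAPK"}

    Returns
    -------
    numpy.ndarray of shape (6,)
    """
    try:
        return np.asarray(IDEAL_PROFILES[interval], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown epistasis interval {interval!r}; "
            f"expected one of {INTERVALS}"
        ) from None


def weighted_uncentered_pearson(x, y, w=None) -> float:
    """Weighted uncentered Pearson correlation between two profiles.

    Unlike the ordinary Pearson correlation the vectors are not
    mean-centered, so the statistic behaves like a weighted cosine
    similarity: r = 1 exactly when ``x`` is a positive multiple of ``y``
    on the support of ``w``, and r = -1 for a negative multiple.

    Parameters
    ----------
    x, y : array-like of shape (n,)
        Profiles to compare.
    w : array-like of shape (n,), optional
        Nonnegative assay weights. Defaults to the screen panel weights
        ``(3, 1, 1, 1, 1, 2)`` when ``n == 6``, else uniform weights.

    Returns
    -------
    float in [-1, 1]

    Raises
    ------
    ZeroNormError
        If either vector has zero weighted norm: r is then undefined,
        which is distinct from r = 0 (orthogonal profiles).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-d of equal length, got {x.shape} and {y.shape}")
    if w is None:
        w = np.asarray(DEFAULT_WEIGHTS) if x.size == 6 else np.ones_like(x)
    w = np.asarray(w, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"w must match x, got {w.shape} vs {x.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    sxx = float(np.sum(w * x * x))
    syy = float(np.sum(w * y * y))
    if sxx == 0.0 or syy == 0.0:
        raise ZeroNormError("zero-norm vector under the given weights; r undefined")
    r = float(np.sum(w * x * y)) / np.sqrt(sxx * syy)
    # guard against fp overshoot only
    return float(min(1.0, max(-1.0, r)))


@dataclass(frozen=True)
class EpistasisPanel:
    """The assay panel against which profiles are classified.

    Attributes
    ----------
    assays : ordered assay names (fixed order carries the weights)
    weights : nonnegative per-assay weights, sum > 0
    profiles : mapping interval -> idealized six-vector
    """

    assays: tuple[str, ...] = EPISTASIS_ASSAYS
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(IDEAL_PROFILES)
    )

    def __post_init__(self):
        n = len(self.assays)
        if len(self.weights) != n:
            raise ValueError("weights length must match assay count")
        if any(v < 0 for v in self.weights) or sum(self.weights) <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        for name, prof in self.profiles.items():
            if len(prof) != n:
                raise ValueError(f"profile {name!r} has wrong length")

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _profile_matrix(X, assays: tuple[str, ...]) -> tuple[np.ndarray, pd.Index]:
    """Coerce profile input to (values, gene index), validating assay names."""
    if isinstance(X, pd.DataFrame):
        missing = [a for a in assays if a not in X.columns]
        if missing:
            raise ValueError(f"missing assay column(s): {missing}")
        return X[list(assays)].to_numpy(dtype=float), X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != len(assays):
        raise ValueError(f"expected {len(assays)} assay columns, got {arr.shape[1]}")
    return arr, pd.RangeIndex(arr.shape[0])


def classify_profiles(
    X,
    panel: EpistasisPanel | None = None,
    unassigned_band: float = 0.5,
    ambiguity_threshold: float = 0.2,
) -> pd.DataFrame:
    """Assign genes to epistasis intervals from their six-assay profiles.

    For each gene the correlation r to the three interval profiles is
    computed; genes whose three correlations all fall inside the
    ``[-unassigned_band, unassigned_band]`` grey band are left unassigned
    ("?").  Otherwise the interval with the largest |r| is chosen; the
    regulator sign is read from the sign of that r (negative r = positive
    regulator), and the confidence score ``|r_best| - |r_second|`` flags
    calls below ``ambiguity_threshold`` as ambiguous ("(A)").

    Returns
    -------
    pandas.DataFrame indexed like ``X`` with columns
    ``r_ras_raf, r_raf_mek, r_mek_mapk, interval, sign, confidence, status``.
    Genes with missing (NaN) assay values raise; genes whose profile is
    identically zero are reported unassigned with NaN correlations.
    """
    panel = panel or EpistasisPanel()
    values, index = _profile_matrix(X, panel.assays)
    if np.isnan(values).any():
        bad = index[np.isnan(values).any(axis=1)]
        if isinstance(X, pd.DataFrame):
            cols = [panel.assays[j] for j in np.where(np.isnan(values).any(axis=0))[0]]
            raise ValueError(f"missing assay value(s) in {cols} for genes {list(bad)}")
        raise ValueError(f"missing assay value(s) for rows {list(bad)}")

    w = panel.weight_array
    prof = np.asarray([panel.profiles[i] for i in INTERVALS], dtype=float)  # (3, 6)
    # r[g, i] = sum(w x y) / sqrt(sum(w x^2) sum(w y^2))
    num = (values * w) @ prof.T
    xnorm = np.sqrt(np.sum(w * values**2, axis=1))
    ynorm = np.sqrt(np.sum(w * prof**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.outer(xnorm, ynorm)
    r = np.clip(r, -1.0, 1.0)

    rows = []
    for g in range(r.shape[0]):
        rg = r[g]
        if xnorm[g] == 0.0 or not np.all(np.isfinite(rg)):
            rows.append((np.nan, np.nan, np.nan, UNASSIGNED, "", np.nan, "unassigned"))
            continue
        a = np.abs(rg)
        if np.all(a <= unassigned_band):
            rows.append((*rg, UNASSIGNED, "", np.nan, "unassigned"))
            continue
        order = np.argsort(-a, kind="stable")  # stable: ties go to interval order
        best, second = order[0], order[1]
        confidence = float(a[best] - a[second])
        interval = INTERVALS[best]
        sign = "positive" if rg[best] < 0 else "negative"
        status = "ambiguous" if confidence < ambiguity_threshold else "assigned"
        rows.append((*rg, interval, sign, confidence, status))

    return pd.DataFrame(
        rows,
        index=index,
        columns=[
            "r_ras_raf",
            "r_raf_mek",
            "r_mek_mapk",
            "interval",
            "sign",
            "confidence",
            "status",
        ],
    )


def classify_gene(profile, panel: EpistasisPanel | None = None, **kwargs) -> pd.Series:
    """Classify a single six-assay profile; see :func:`classify_profiles`."""
    out = classify_profiles(np.asarray(profile, dtype=float).reshape(1, -1), panel, **kwargs)
    return out.iloc[0]


def interval_census(calls: pd.DataFrame) -> pd.DataFrame:
    """Tabulate epistasis calls by interval, regulator sign, and status.

    Parameters
    ----------
    calls : DataFrame as returned by :func:`classify_profiles`.

    Returns
    -------
    DataFrame with columns ``interval, sign, status, n``; the ``n`` column
    sums to ``len(calls)``.
    """
    if calls.empty:
        return pd.DataFrame(columns=["interval", "sign", "status", "n"])
    out = (
        calls.groupby(["interval", "sign", "status"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["interval", "sign", "status"], kind="stable")
        .reset_index(drop=True)
    )
    assert int(out["n"].sum()) == len(calls)
    return out


class EpistasisClassifier(BaseEstimator):
    """Rule-based interval classifier over six-assay epistasis profiles.

    A scikit-learn-style estimator wrapping :func:`classify_profiles`.
    ``fit`` only validates the panel (the rule has no trainable state);
    ``predict`` returns the interval labels and ``decision_function`` the
    signed correlations to the three interval profiles.

    Parameters
    ----------
    weights : per-assay weights, default ``(3, 1, 1, 1, 1, 2)``.
    unassigned_band : half-width of the grey band; a gene is unassigned
        when every |r| is at or below it. Default 0.5.
    ambiguity_threshold : confidence below which a call is flagged
        ambiguous. Default 0.2.
    """

    def __init__(
        self,
        weights: tuple[float, ...] = DEFAULT_WEIGHTS,
        unassigned_band: float = 0.5,
        ambiguity_threshold: float = 0.2,
    ):
        self.weights = weights
        self.unassigned_band = unassigned_band
        self.ambiguity_threshold = ambiguity_threshold

    def fit(self, X, y=None):
        """Validate the panel against ``X``'s assay columns."""
        self.panel_ = EpistasisPanel(weights=tuple(self.weights))
        _profile_matrix(X, self.panel_.assays)  # validates shape/columns
        self.classes_ = np.asarray(list(INTERVALS) + [UNASSIGNED])
        self.n_features_in_ = len(self.panel_.assays)
        return self

    def classify(self, X) -> pd.DataFrame:
        """Full call table: correlations, interval, sign, confidence, status."""
        check_is_fitted(self, "panel_")
        return classify_profiles(
            X,
            self.panel_,
            unassigned_band=self.unassigned_band,
            ambiguity_threshold=self.ambiguity_threshold,
        )

    def predict(self, X) -> np.ndarray:
        """Interval label per gene ("?" for unassigned)."""
        return self.classify(X)["interval"].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        """Signed correlations to the three interval profiles, shape (n, 3)."""
        return self.classify(X)[["r_ras_raf", "r_raf_mek", "r_mek_mapk"]].to_numpy()
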