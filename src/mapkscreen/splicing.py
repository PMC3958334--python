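"""Splice-isoform ORF-consequence classification.

Sequenced RT-PCR clones of a transcript are summarized as exon
inclusion/skipping patterns (1/0 per annotated exon, plus optionally
retained introns).  Each pattern is classified by what it does to the
open reading frame:

- ``N`` (normal): every CDS-bearing exon included, no CDS-internal intron
  retained — the encoded protein is unchanged.
- ``no_start``: the exon carrying the start codon is skipped; no product
  can initiate (reported alongside frameshifted products in summaries).
- ``F`` (frameshifted): the skipped CDS length (plus any retained
  CDS-internal intron length) is not a multiple of 3, or the exon
  carrying the stop codon is skipped (read-through).
- ``T`` (truncated/in-frame): CDS nucleotides are removed or inserted in
  multiples of 3 with start and stop context intact.

UTR-only changes (skipping a pure-UTR exon, retaining a UTR intron such
as a retained first intron upstream of the start codon) leave the product
normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

PRODUCT_CLASSES = ("N", "T", "F", "no_start")


@dataclass(frozen=True)
class ExonModel:
    """Transcript exon architecture with CDS anchors.

    Attributes
    ----------
    exon_ids : exon names ordered 5' -> 3'.
    exon_lengths : exon lengths in nt, all > 0.
    cds_start : (exon_id, offset) of the first CDS nucleotide
        (0-based offset within the exon).
    cds_end : (exon_id, offset) of the last CDS nucleotide (inclusive;
        the final base of the stop codon).
    intron_lengths : optional lengths of the len(exons)-1 introns, needed
        only when retained introns are to be classified.
    """

    exon_ids: tuple[str, ...]
    exon_lengths: tuple[int, ...]
    cds_start: tuple[str, int]
    cds_end: tuple[str, int]
    intron_lengths: tuple[int, ...] | None = None

    def __post_init__(self):
        if len(self.exon_ids) != len(self.exon_lengths):
            raise ValueError("exon_ids and exon_lengths length mismatch")
        if len(set(self.exon_ids)) != len(self.exon_ids):
            raise ValueError("duplicate exon ids")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if self.intron_lengths is not None and len(self.intron_lengths) != len(self.exon_ids) - 1:
            raise ValueError("need len(exons)-1 intron lengths")
        for anchor in (self.cds_start, self.cds_end):
            i = self.exon_index(anchor[0])
            if not (0 <= anchor[1] < self.exon_lengths[i]):
                raise ValueError(f"CDS anchor offset out of exon: {anchor}")
        if self.cds_start_tpos >= self.cds_end_tpos:
            raise ValueError("cds_start must precede cds_end in transcript coordinates")

    def exon_index(self, exon_id: str) -> int:
        try:
            return self.exon_ids.index(exon_id)
        except ValueError:
            raise ValueError(f"unknown exon id {exon_id!r}") from None

    @property
    def exon_starts(self) -> np.ndarray:
        """Transcript-coordinate start of each exon in the full transcript."""
        return np.concatenate([[0], np.cumsum(self.exon_lengths)[:-1]])

    @property
    def cds_start_tpos(self) -> int:
        """0-based transcript position of the first CDS nucleotide."""
        i = self.exon_index(self.cds_start[0])
        return int(self.exon_starts[i]) + self.cds_start[1]

    @property
    def cds_end_tpos(self) -> int:
        """0-based transcript position of the last CDS nucleotide."""
        i = self.exon_index(self.cds_end[0])
        return int(self.exon_starts[i]) + self.cds_end[1]

    def cds_overlap(self, exon_index: int) -> int:
        """Number of CDS nucleotides carried by the given exon."""
        start = int(self.exon_starts[exon_index])
        end = start + self.exon_lengths[exon_index]  # exclusive
        lo = max(start, self.cds_start_tpos)
        hi = min(end, self.cds_end_tpos + 1)
        return max(0, hi - lo)


@dataclass(frozen=True)
class InclusionPattern:
    """Observed exon inclusion mask plus optionally retained introns.

    ``mask[i]`` is True when exon i is present in the clone;
    ``retained_introns`` holds intron indices (intron i separates exons i
    and i+1).
    """

    mask: tuple[bool, ...]
    retained_introns: tuple[int, ...] = field(default_factory=tuple)


def classify_splice_product(model: ExonModel, pattern: InclusionPattern) -> str:
    """Classify an inclusion pattern as ``N``, ``T``, ``F`` or ``no_start``.

    Raises
    ------
    ValueError
        On a mask/model length mismatch, a retained-intron index without
        intron lengths or with a skipped flanking exon, or an invalid
        intron index.
    """
    mask = tuple(bool(m) for m in pattern.mask)
    if len(mask) != len(model.exon_ids):
        raise ValueError(
            f"pattern has {len(mask)} exons but model has {len(model.exon_ids)}"
        )
    for i in pattern.retained_introns:
        if not (0 <= i < len(model.exon_ids) - 1):
            raise ValueError(f"intron index {i} out of range")
        if model.intron_lengths is None:
            raise ValueError("retained introns given but model has no intron lengths")
        if not (mask[i] and mask[i + 1]):
            raise ValueError(f"retained intron {i} flanked by a skipped exon")

    start_idx = model.exon_index(model.cds_start[0])
    if not mask[start_idx]:
        return "no_start"
    end_idx = model.exon_index(model.cds_end[0])
    if not mask[end_idx]:
        return "F"  # stop codon lost: read-through product

    removed = sum(
        model.cds_overlap(i) for i, included in enumerate(mask) if not included
    )
    cs, ce = model.cds_start_tpos, model.cds_end_tpos
    inserted = 0
    for i in pattern.retained_introns:
        junction = int(model.exon_starts[i]) + model.exon_lengths[i]
        if cs < junction <= ce:  # insertion lands inside the CDS
            inserted += model.intron_lengths[i]
    # removals shift downstream phase by -removed, insertions by +inserted
    if (inserted - removed) % 3 != 0:
        return "F"
    if removed + inserted > 0:
        return "T"
    return "N"


def patterns_from_table(table: pd.DataFrame, model: ExonModel) -> list[InclusionPattern]:
    """Build patterns from a clone x exon 0/1 table (columns = exon ids)."""
    missing = [e for e in model.exon_ids if e not in table.columns]
    if missing:
        raise ValueError(f"inclusion table missing exon column(s): {missing}")
    mat = table[list(model.exon_ids)].to_numpy()
    return [InclusionPattern(tuple(bool(v) for v in row)) for row in mat]


def mapk_like_model() -> ExonModel:
    """Synthetic eight-exon model with mapk-like frame properties.

    The real transcript's exon lengths are not used here; this synthetic
    stand-in reproduces the qualitative architecture the classifier is
    exercised against: exon I is untranslated, exon II carries the start
    codon, exons IV and VII have lengths divisible by 3 (their skipping
    yields in-frame deletions), exons III and V do not (frameshift), and
    exon VIII carries the stop.  The long first intron mimics a retained
    5'UTR intron (no ORF consequence).
    """
    return ExonModel(
        exon_ids=("I", "II", "III", "IV", "V", "VI", "VII", "VIII"),
        exon_lengths=(150, 200, 140, 120, 100, 130, 90, 300),
        cds_start=("II", 50),
        cds_end=("VIII", 100),
        intron_lengths=(1000, 75, 62, 58, 64, 70, 80),
    )


class SpliceClassifier(BaseEstimator):
    """Estimator wrapper classifying inclusion patterns against one model.

    Parameters
    ----------
    model : ExonModel, default the synthetic mapk-like fixture.
    """

    def __init__(self, model: ExonModel | None = None):
        self.model = model

    def fit(self, X=None, y=None):
        self.model_ = self.model if self.model is not None else mapk_like_model()
        self.classes_ = np.asarray(PRODUCT_CLASSES)
        return self

    def predict(self, X) -> np.ndarray:
        """Classify patterns (InclusionPattern list, boolean matrix, or
        a clone x exon 0/1 DataFrame)."""
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            patterns = patterns_from_table(X, self.model_)
        else:
            patterns = [
                p if isinstance(p, InclusionPattern) else InclusionPattern(tuple(bool(v) for v in p))
                for p in X
            ]
        return np.asarray([classify_splice_product(self.model_, p) for p in patterns])
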