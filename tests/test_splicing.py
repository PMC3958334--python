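"""Splice-product classification vs an independent translation oracle.

The oracle builds concrete nucleotide sequences for random toy transcripts
(general alphabet {C, G}, so the only stop codon anywhere in any frame is
the single TAA placed at the CDS end), splices them by explicit string
concatenation, locates the start codon, translates codon by codon, and
classifies the product by comparing the translated CDS with the full-
inclusion CDS — an entirely separate code path from the arithmetic
classifier.
"""

import numpy as np
import pytest

from mapkscreen import (
    ExonModel,
    InclusionPattern,
    SpliceClassifier,
    classify_splice_product,
    mapk_like_model,
)

STOPS = {"TAA", "TAG", "TGA"}


# --------------------------------------------------------------------------
# independent oracle
# --------------------------------------------------------------------------

def build_sequences(model: ExonModel, rng) -> tuple[list[str], list[str]]:
    """Random exon/intron sequences over {C, G} with ATG/TAA placed."""
    nts = np.array(list("CG"))
    exon_seqs = ["".join(rng.choice(nts, size=l)) for l in model.exon_lengths]
    intron_seqs = ["".join(rng.choice(nts, size=l)) for l in (model.intron_lengths or [])]
    si = model.exon_index(model.cds_start[0])
    o = model.cds_start[1]
    s = list(exon_seqs[si])
    s[o : o + 3] = "ATG"
    exon_seqs[si] = "".join(s)
    ei = model.exon_index(model.cds_end[0])
    e = model.cds_end[1]
    s = list(exon_seqs[ei])
    s[e - 2 : e + 1] = "TAA"
    exon_seqs[ei] = "".join(s)
    return exon_seqs, intron_seqs


def splice(model, pattern, exon_seqs, intron_seqs) -> str:
    parts = []
    retained = set(pattern.retained_introns)
    for i, included in enumerate(pattern.mask):
        if included:
            parts.append(exon_seqs[i])
        if i in retained:
            parts.append(intron_seqs[i])
    return "".join(parts)


def oracle_classify(model, pattern, exon_seqs, intron_seqs) -> str:
    full = splice(
        model, InclusionPattern(tuple([True] * len(model.exon_ids))), exon_seqs, []
    )
    cds_full = full[model.cds_start_tpos : model.cds_end_tpos + 1]
    assert cds_full.startswith("ATG") and cds_full.endswith("TAA")
    assert len(cds_full) % 3 == 0

    seq = splice(model, pattern, exon_seqs, intron_seqs)
    start = seq.find("ATG")
    if start == -1:
        return "no_start"
    stop = None
    j = start
    while j + 3 <= len(seq):
        if seq[j : j + 3] in STOPS:
            stop = j
            break
        j += 3
    if stop is None:
        return "F"
    observed_cds = seq[start : stop + 3]
    return "N" if observed_cds == cds_full else "T"


def random_model(rng) -> ExonModel:
    while True:
        n = int(rng.integers(3, 9))
        lengths = tuple(int(v) for v in rng.integers(9, 61, size=n))
        si = int(rng.integers(0, n))
        if lengths[si] < 7:
            continue
        o = int(rng.integers(0, lengths[si] - 3))  # ATG fully inside exon si
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        cs = starts[si] + o
        candidates = []
        for ei in range(si, n):
            e_lo = 2 if ei != si else o + 5
            for e in range(e_lo, lengths[ei]):
                ce = starts[ei] + e
                cds_len = ce - cs + 1
                if cds_len >= 6 and cds_len % 3 == 0:
                    candidates.append((ei, e))
        if not candidates:
            continue
        ei, e = candidates[int(rng.integers(0, len(candidates)))]
        introns = tuple(int(v) for v in rng.integers(5, 41, size=n - 1))
        ids = tuple(f"E{i + 1}" for i in range(n))
        return ExonModel(ids, lengths, (ids[si], o), (ids[ei], e), introns)


def random_pattern(model, rng) -> InclusionPattern:
    n = len(model.exon_ids)
    mask = tuple(bool(v) for v in rng.random(n) < 0.75)
    retained = []
    if rng.random() < 0.3:
        eligible = [i for i in range(n - 1) if mask[i] and mask[i + 1]]
        if eligible:
            k = min(len(eligible), int(rng.integers(1, 3)))
            retained = sorted(rng.choice(eligible, size=k, replace=False).tolist())
    return InclusionPattern(mask, tuple(int(i) for i in retained))


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

class TestFixtureModel:
    @pytest.fixture()
    def model(self):
        return mapk_like_model()

    def full_mask(self, model, skip=()):
        return InclusionPattern(
            tuple(eid not in skip for eid in model.exon_ids)
        )

    def test_all_exons_included_is_normal(self, model):
        assert classify_splice_product(model, self.full_mask(model)) == "N"

    @pytest.mark.parametrize("exon", ["IV", "VII"])
    def test_in_frame_cds_skip_truncates(self, model, exon):
        assert classify_splice_product(model, self.full_mask(model, {exon})) == "T"

    def test_start_exon_skip_loses_start(self, model):
        assert classify_splice_product(model, self.full_mask(model, {"II"})) == "no_start"

    @pytest.mark.parametrize("exon", ["III", "V"])
    def test_out_of_frame_skip_shifts(self, model, exon):
        assert classify_splice_product(model, self.full_mask(model, {exon})) == "F"

    def test_stop_exon_skip_reads_through(self, model):
        assert classify_splice_product(model, self.full_mask(model, {"VIII"})) == "F"

    def test_utr_exon_skip_is_silent(self, model):
        assert classify_splice_product(model, self.full_mask(model, {"I"})) == "N"

    def test_retained_first_intron_is_silent(self, model):
        pattern = InclusionPattern(tuple([True] * 8), (0,))
        assert classify_splice_product(model, pattern) == "N"

    def test_retained_cds_intron_frame(self, model):
        # intron 1 (75 nt, in frame) -> T; intron 2 (62 nt) -> F
        assert classify_splice_product(model, InclusionPattern((True,) * 8, (1,))) == "T"
        assert classify_splice_product(model, InclusionPattern((True,) * 8, (2,))) == "F"

    def test_fixture_agrees_with_translation_oracle(self, model):
        rng = np.random.default_rng(101)
        exon_seqs, intron_seqs = build_sequences(model, rng)
        for pattern in [
            self.full_mask(model),
            self.full_mask(model, {"IV"}),
            self.full_mask(model, {"II"}),
            self.full_mask(model, {"III"}),
            InclusionPattern((True,) * 8, (0,)),
            InclusionPattern((True,) * 8, (1,)),
        ]:
            assert classify_splice_product(model, pattern) == oracle_classify(
                model, pattern, exon_seqs, intron_seqs
            )


class TestValidation:
    def test_mask_length_mismatch(self):
        model = mapk_like_model()
        with pytest.raises(ValueError, match="exons"):
            classify_splice_product(model, InclusionPattern((True,) * 5))

    def test_retained_intron_needs_included_neighbors(self):
        model = mapk_like_model()
        mask = tuple(eid != "II" for eid in model.exon_ids)
        with pytest.raises(ValueError, match="intron"):
            classify_splice_product(model, InclusionPattern(mask, (1,)))

    def test_intron_index_range(self):
        model = mapk_like_model()
        with pytest.raises(ValueError):
            classify_splice_product(model, InclusionPattern((True,) * 8, (9,)))

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            ExonModel(("a", "b"), (10, -5), ("a", 0), ("b", 2))
        with pytest.raises(ValueError):
            ExonModel(("a", "b"), (10, 10), ("b", 5), ("a", 2))  # start after end
        with pytest.raises(ValueError):
            ExonModel(("a", "a"), (10, 10), ("a", 0), ("a", 8))


class TestRandomOracleAgreement:
    def test_agreement_on_random_models(self):
        """Arithmetic classifier agrees with the translation oracle across
        random exon architectures and inclusion patterns."""
        rng = np.random.default_rng(211)
        checked = 0
        for _ in range(250):
            model = random_model(rng)
            exon_seqs, intron_seqs = build_sequences(model, rng)
            for _ in range(4):
                pattern = random_pattern(model, rng)
                expected = oracle_classify(model, pattern, exon_seqs, intron_seqs)
                assert classify_splice_product(model, pattern) == expected
                checked += 1
        assert checked == 1000


class TestSpliceClassifierEstimator:
    def test_predict_on_inclusion_table(self):
        import pandas as pd

        model = mapk_like_model()
        table = pd.DataFrame(
            [
                {eid: 1 for eid in model.exon_ids},
                {eid: (0 if eid == "IV" else 1) for eid in model.exon_ids},
                {eid: (0 if eid == "II" else 1) for eid in model.exon_ids},
            ]
        )
        clf = SpliceClassifier().fit()
        assert clf.predict(table).tolist() == ["N", "T", "no_start"]

    def test_predict_on_masks(self):
        clf = SpliceClassifier(model=mapk_like_model()).fit()
        out = clf.predict([[1, 1, 1, 1, 1, 1, 1, 1]])
        assert out.tolist() == ["N"]
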