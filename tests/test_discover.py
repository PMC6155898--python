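import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdckit.discover import (
    DiscoveryConfig,
    LabeledAlignment,
    column_profiles,
    column_to_reference_position,
    extract_motif_pairs,
    find_diagnostic_columns,
)
from tdckit.msa import Alignment
from tdckit.seq_core import GAP, SequenceRecord, TDC, TYDC
from tdckit.synthetic_data import FamilyConfig, MotifLayout, generate_family


def toy_alignment():
    """Mirrors the THW[L/M]SP vs THWQSP discriminative region."""
    rows = [
        SequenceRecord(id="a1", residues="THWLSP", class_label=TDC),
        SequenceRecord(id="a2", residues="TNWMSP", class_label=TDC),
        SequenceRecord(id="b1", residues="THWQSP", class_label=TYDC),
        SequenceRecord(id="b2", residues="THWQSP", class_label=TYDC),
    ]
    return LabeledAlignment(Alignment(rows))


class TestLabeledAlignment:
    def test_single_class_rejected(self):
        rows = [
            SequenceRecord(id="a", residues="ACD", class_label=TDC),
            SequenceRecord(id="b", residues="ACD", class_label=TDC),
        ]
        with pytest.raises(ValueError, match="two classes"):
            LabeledAlignment(Alignment(rows))

    def test_sparse_class_rejected(self):
        rows = [
            SequenceRecord(id="a", residues="ACD", class_label=TDC),
            SequenceRecord(id="b", residues="ACD", class_label=TDC),
            SequenceRecord(id="c", residues="ACD", class_label=TYDC),
        ]
        with pytest.raises(ValueError, match="fewer than 2"):
            LabeledAlignment(Alignment(rows))


class TestColumnProfiles:
    def test_frequencies(self):
        rows = [
            SequenceRecord(id="a1", residues="L", class_label=TDC),
            SequenceRecord(id="a2", residues="L", class_label=TDC),
            SequenceRecord(id="a3", residues="M", class_label=TDC),
            SequenceRecord(id="b1", residues="Q", class_label=TYDC),
            SequenceRecord(id="b2", residues="Q", class_label=TYDC),
        ]
        profs = column_profiles(LabeledAlignment(Alignment(rows)))
        assert profs[0].frequencies[TDC] == pytest.approx({"L": 2 / 3, "M": 1 / 3})
        assert profs[0].frequencies[TYDC] == {"Q": 1.0}

    def test_gap_fraction(self):
        rows = [
            SequenceRecord(id="a1", residues="-A", class_label=TDC),
            SequenceRecord(id="a2", residues="-A", class_label=TDC),
            SequenceRecord(id="b1", residues="CA", class_label=TYDC),
            SequenceRecord(id="b2", residues="CA", class_label=TYDC),
        ]
        profs = column_profiles(LabeledAlignment(Alignment(rows)))
        assert profs[0].gap_fraction[TDC] == 1.0
        assert profs[0].frequencies[TDC] == {}

    def test_planted_profiles_match_generator(self, sigs):
        """Class-consensus columns reflect the planted motif emission sets."""
        seqs, truth = generate_family(FamilyConfig(n_tdc=8, n_tydc=8, mu=0.0, seed=4))
        la = LabeledAlignment(Alignment(list(seqs)))
        profs = column_profiles(la)
        # the SP of SPHKW at TDC anchor 318: every TDC row has S then P
        assert profs[317].frequencies[TDC] == {"S": 1.0}
        assert profs[318].frequencies[TDC] == {"P": 1.0}
        # backbone column (untouched at mu=0): identical in both classes
        col0 = 0
        assert profs[col0].frequencies[TDC] == profs[col0].frequencies[TYDC]


class TestDiagnosticColumns:
    def test_toy_yields_only_the_q_column(self):
        assert find_diagnostic_columns(toy_alignment()) == [4]

    def test_identical_consensus_yields_nothing(self):
        rows = [
            SequenceRecord(id="a1", residues="ACDEF", class_label=TDC),
            SequenceRecord(id="a2", residues="ACDEF", class_label=TDC),
            SequenceRecord(id="b1", residues="ACDEF", class_label=TYDC),
            SequenceRecord(id="b2", residues="ACDEF", class_label=TYDC),
        ]
        assert find_diagnostic_columns(LabeledAlignment(Alignment(rows))) == []

    def test_exact_recovery_at_zero_noise(self):
        for seed in (0, 1, 2):
            seqs, truth = generate_family(FamilyConfig(mu=0.0, seed=seed))
            la = LabeledAlignment(Alignment(list(seqs)))
            assert set(find_diagnostic_columns(la)) == set(truth.diagnostic_columns)

    def test_label_swap_leaves_columns_unchanged(self):
        seqs, _ = generate_family(FamilyConfig(n_tdc=4, n_tydc=4, mu=0.05, seed=6))
        la = LabeledAlignment(Alignment(list(seqs)))
        flipped = Alignment(
            [
                SequenceRecord(
                    id=r.id,
                    residues=r.residues,
                    class_label=TYDC if r.class_label == TDC else TDC,
                )
                for r in seqs
            ]
        )
        assert find_diagnostic_columns(la) == find_diagnostic_columns(
            LabeledAlignment(flipped)
        )


class TestMotifPairs:
    def test_toy_reproduces_the_thwqsp_pair(self):
        pairs = extract_motif_pairs(toy_alignment())
        assert len(pairs) == 1
        assert pairs[0].patterns[TDC] == "T[H/N]W[L/M]SP"
        assert pairs[0].patterns[TYDC] == "THWQSP"
        assert pairs[0].diagnostic_columns == (4,)
        assert pairs[0].span == (1, 6)

    def test_no_diagnostic_columns_no_pairs(self):
        rows = [
            SequenceRecord(id="a1", residues="ACDEF", class_label=TDC),
            SequenceRecord(id="a2", residues="ACDEF", class_label=TDC),
            SequenceRecord(id="b1", residues="ACDEF", class_label=TYDC),
            SequenceRecord(id="b2", residues="ACDEF", class_label=TYDC),
        ]
        assert extract_motif_pairs(LabeledAlignment(Alignment(rows))) == []

    def test_pair_diagnostics_subset_of_column_scan(self):
        seqs, _ = generate_family(FamilyConfig(n_tdc=6, n_tydc=6, mu=0.05, seed=8))
        la = LabeledAlignment(Alignment(list(seqs)))
        cfg = DiscoveryConfig(epsilon=0.1)
        all_diag = set(find_diagnostic_columns(la, cfg))
        for pair in extract_motif_pairs(la, cfg):
            assert set(pair.diagnostic_columns) <= all_diag

    def test_planted_blocks_recovered_with_colocated_motifs(self, sigs):
        """With class motifs in the same columns and a noisy backbone, the
        discriminative planted blocks come back at their planted spans.

        The third packaged pair has no disjoint column (its variants overlap
        at every offset), so it is correctly *not* reported — a conserved run
        qualifies only if it contains a diagnostic column.
        """
        layout = MotifLayout(
            signatures=sigs, tdc_anchors=(92, 103, 167, 318), tydc_anchors=(92, 103, 167, 318)
        )
        seqs, _ = generate_family(
            FamilyConfig(n_tdc=12, n_tydc=12, mu=0.45, seed=5, motif_layout=layout)
        )
        la = LabeledAlignment(Alignment(list(seqs)))
        pairs = extract_motif_pairs(la, DiscoveryConfig(merge_gap=0))
        spans = [p.span for p in pairs]
        assert spans == [(92, 97), (103, 112), (318, 322)]

    def test_discovered_pairs_load_into_classifier(self):
        pairs = extract_motif_pairs(toy_alignment())
        sp = pairs[0].as_signature_pair(TDC, TYDC)
        from tdckit.signatures import diagnostic_positions

        assert diagnostic_positions(sp) == {4}


class TestReferencePositions:
    def test_examples(self):
        aln = Alignment(
            [
                SequenceRecord(id="r", residues="AC-C"),
                SequenceRecord(id="s", residues="ACCC"),
            ]
        )
        assert column_to_reference_position(aln, "r", 4) == 3
        assert column_to_reference_position(aln, "r", 1) == 1

    def test_gap_cell_rejected(self):
        aln = Alignment([SequenceRecord(id="r", residues="A-C"), SequenceRecord(id="s", residues="AAC")])
        with pytest.raises(ValueError, match="gap"):
            column_to_reference_position(aln, "r", 2)

    @settings(deadline=None, max_examples=40)
    @given(st.text(alphabet="AC-", min_size=1, max_size=30), st.data())
    def test_agrees_with_prefix_count(self, row, data):
        if set(row) <= {"-"}:
            row = row + "A"
        filler = SequenceRecord(id="s", residues="A" * len(row))
        aln = Alignment([SequenceRecord(id="r", residues=row), filler])
        nongap_cols = [i + 1 for i, ch in enumerate(row) if ch != GAP]
        col = data.draw(st.sampled_from(nongap_cols))
        brute = sum(1 for ch in row[:col] if ch != GAP)
        assert column_to_reference_position(aln, "r", col) == brute
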