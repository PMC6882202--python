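"""Unit tests for mutant construction, window enumeration and redundancy collapse."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from recurneo import peptides
from recurneo.peptides import (MutantContext, ProteinSequence,
                               apply_variant_to_protein, collapse_redundancy,
                               enumerate_windows, filter_binders)
from recurneo.predictors import BindingPrediction, TablePredictor
from recurneo.variant_filtering import ProteinChange
import pandas as pd


def brute_force_windows(length, pos, lengths=(9, 10, 11)):
    """Slide every window of each length; count those covering pos."""
    out = []
    for k in lengths:
        for s in range(1, length - k + 2):
            if s <= pos <= s + k - 1:
                out.append((k, s))
    return out


def make_context(length=30, pos=15):
    wild = "".join(random.Random(7).choices("ACDEFGHIKLMNPQRSTVWY", k=length))
    alt = "W" if wild[pos - 1] != "W" else "Y"
    change = ProteinChange("G1", pos, wild[pos - 1], alt)
    return apply_variant_to_protein(ProteinSequence("G1", wild), change), change


class TestApplyVariant:
    def test_substitutes_single_residue(self):
        ctx = apply_variant_to_protein(ProteinSequence("g", "ARNDS"),
                                       ProteinChange("g", 5, "S", "L"))
        assert ctx.mutant.residues == "ARNDL"
        assert ctx.wild.residues == "ARNDS"

    def test_reference_mismatch_names_residues(self):
        with pytest.raises(ValueError, match="expected T, found S"):
            apply_variant_to_protein(ProteinSequence("g", "ARNDS"),
                                     ProteinChange("g", 5, "T", "L"))

    def test_out_of_range_position(self):
        with pytest.raises(ValueError, match="outside"):
            apply_variant_to_protein(ProteinSequence("g", "ARNDS"),
                                     ProteinChange("g", 9, "S", "L"))


class TestEnumerateWindows:
    def test_interior_position_yields_30_windows(self):
        ctx, _ = make_context(30, 15)
        assert len(enumerate_windows(ctx)) == 30

    def test_n_terminus_yields_one_window_per_length(self):
        ctx, _ = make_context(30, 1)
        windows = enumerate_windows(ctx)
        assert len(windows) == 3
        assert all(w.start == 1 for w in windows)

    def test_protein_of_length_nine(self):
        ctx, _ = make_context(23, 12)
        # restrict to a 9-mer protein by enumerating only length 9 on a 9-long protein
        wild = "ARNDCEQGH"
        change = ProteinChange("g", 5, "C", "W")
        ctx = apply_variant_to_protein(ProteinSequence("g", wild), change)
        assert len(enumerate_windows(ctx)) == 1

    @settings(derandomize=True, max_examples=120)
    @given(length=st.integers(9, 40), data=st.data())
    def test_matches_brute_force_slider_everywhere(self, length, data):
        pos = data.draw(st.integers(1, length))
        wild = ("ACDEFGHIKLMNPQRSTVWY" * 2)[:length]
        alt = "W" if wild[pos - 1] != "W" else "Y"
        ctx = apply_variant_to_protein(
            ProteinSequence("g", wild), ProteinChange("g", pos, wild[pos - 1], alt))
        got = [(w.length, w.start) for w in enumerate_windows(ctx)]
        assert sorted(got) == sorted(brute_force_windows(length, pos))
        for w in enumerate_windows(ctx):
            assert w.sequence[w.variant_offset - 1] == alt


class TestCollapseRedundancy:
    def test_lowest_mutant_ic50_retained(self):
        ctx, change = make_context(30, 15)
        windows = enumerate_windows(ctx)[:3]
        preds = [BindingPrediction(w.sequence, "HLA-A*02:01", ic50, "weak")
                 for w, ic50 in zip(windows, (30.0, 8.8, 500.0))]
        out = collapse_redundancy(windows, preds, change)
        assert out["HLA-A*02:01"].mut_ic50_nm == 8.8

    def test_single_window_is_its_own_best(self):
        ctx, change = make_context(30, 15)
        w = enumerate_windows(ctx)[0]
        pred = BindingPrediction(w.sequence, "A", 42.0, "non")
        out = collapse_redundancy([w], [pred], change)
        assert out["A"].window == w

    def test_equals_exhaustive_argmin_and_is_order_invariant(self):
        ctx, change = make_context(40, 20)
        windows = enumerate_windows(ctx)
        rnd = random.Random(5)
        preds = [BindingPrediction(w.sequence, "A", rnd.uniform(1, 5e4), "non")
                 for w in windows]
        best = min(zip(preds, windows),
                   key=lambda pw: (pw[0].ic50_nm, pw[1].length, pw[1].start))
        out = collapse_redundancy(windows, preds, change)
        assert out["A"].mut_ic50_nm == best[0].ic50_nm
        shuffled = preds[:]
        rnd.shuffle(shuffled)
        assert collapse_redundancy(windows, shuffled, change) == out

    def test_retained_peptide_carries_alternate_residue(self, toy_predictor):
        ctx, change = make_context(35, 18)
        windows = enumerate_windows(ctx)
        preds = peptides.predict_bindings(windows, ["HLA-A*02:01"], toy_predictor)
        out = collapse_redundancy(windows, preds, change)
        cand = out["HLA-A*02:01"]
        assert cand.window.sequence[cand.window.variant_offset - 1] == change.alt_aa


class TestWildType:
    def test_wild_type_peptide_differs_only_at_variant_offset(self, toy_predictor):
        ctx, change = make_context(30, 15)
        windows = enumerate_windows(ctx)
        preds = peptides.predict_bindings(windows, ["HLA-B*07:02"], toy_predictor)
        cand = collapse_redundancy(windows, preds, change)["HLA-B*07:02"]
        done = peptides.attach_wild_type(cand, ctx, toy_predictor)
        w = done.window
        wt = ctx.wild.residues[w.start - 1:w.start - 1 + w.length]
        diffs = [i for i, (a, b) in enumerate(zip(wt, w.sequence)) if a != b]
        assert diffs == [w.variant_offset - 1]
        assert done.wt_ic50_nm > 0


class TestPredictBindings:
    def test_cardinality_windows_times_alleles(self, toy_predictor):
        ctx, _ = make_context(30, 15)
        windows = enumerate_windows(ctx)
        alleles = ["HLA-A*02:01", "HLA-B*07:02"]
        preds = peptides.predict_bindings(windows, alleles, toy_predictor)
        assert len(preds) == len(windows) * len(alleles)

    def test_determinism_per_pair(self, toy_predictor):
        a = toy_predictor.predict("KLLEIFTEL", "HLA-A*02:01")
        b = toy_predictor.predict("KLLEIFTEL", "HLA-A*02:01")
        assert a == b


class TestFilterBinders:
    def test_keep_classes(self):
        ctx, change = make_context(30, 15)
        w = enumerate_windows(ctx)[0]
        cands = [peptides.NeoEpitopeCandidate(change, f"A{i}", w, 10.0, cls)
                 for i, cls in enumerate(("strong", "weak", "non"))]
        assert len(filter_binders(cands, {"strong"})) == 1
        assert len(filter_binders(cands, {"strong", "weak"})) == 2
        assert filter_binders([], {"strong"}) == []


class TestTableAdapter:
    def test_netmhccons_table_roundtrip(self, tmp_path):
        path = tmp_path / "preds.txt"
        path.write_text(
            "peptide allele ic50_nm binder_level\n"
            "KLLEIFTEL HLA-A*02:01 8.8 SB\n"
            "KLSEIFTEL HLA-A*02:01 1200.0 WB\n"
            "AAAAAAAAA HLA-A*02:01 45000.0 NB\n")
        predictor = TablePredictor.from_file(path)
        strong = predictor.predict("KLLEIFTEL", "HLA-A*02:01")
        assert (strong.ic50_nm, strong.binder_class) == (8.8, "strong")
        assert predictor.predict("KLSEIFTEL", "HLA-A*02:01").binder_class == "weak"
        assert predictor.predict("AAAAAAAAA", "HLA-A*02:01").binder_class == "non"

    def test_missing_pair_raises_with_pair(self, tmp_path):
        predictor = TablePredictor(pd.DataFrame(
            {"peptide": ["AAA"], "allele": ["X"], "ic50_nm": [1.0],
             "binder_level": ["SB"]}))
        with pytest.raises(Exception, match="BBB"):
            predictor.predict("BBB", "X")
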