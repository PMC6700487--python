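import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from conftest import build_hairpin, random_rna, seq_for_dotbracket
from mirhairpin.errors import InputError
from mirhairpin.features import (
    FEATURE_NAMES,
    FeatureVector,
    compute_features,
    feature_manifest,
    read_feature_csv,
    sequence_features,
    structure_features,
    thermo_features,
    triplet_features,
    write_feature_csv,
)
from mirhairpin.folding import EnsembleData, fold_ensemble, fold_mfe
from mirhairpin.hairpin_extraction import compute_stem_stats


def folded_hairpin(seq, **kwargs):
    s = fold_mfe(seq)
    return build_hairpin(seq, s.dotbracket, **kwargs)


class TestCanonicalOrder:
    def test_dimension_and_group_sizes(self):
        assert len(FEATURE_NAMES) == 77
        def group(prefix):
            return [n for n in FEATURE_NAMES if n.startswith(prefix)]
        assert len(group("nt_proportion_")) == 4
        assert len(group("dinucleotide_proportion_")) == 16
        assert len(group("triplets_")) == 32
        assert len(group("bp_proportion_stem_")) == 3
        assert len(group("bp_proportion_")) == 6  # 3 + 3 stem
        for single in ("gc_content", "gc_ratio", "sequence_length", "stem_number",
                       "avg_bp_stem", "longest_stem_length", "terminal_loop_length",
                       "bp_number", "dP", "MFE", "EFE", "ensemble_frequency",
                       "diversity", "mfe_efe_difference", "dQ", "dG",
                       "MFEI_1", "MFEI_2", "MFEI_4"):
            assert FEATURE_NAMES.count(single) == 1

    def test_manifest_matches_code(self):
        assert feature_manifest() == list(FEATURE_NAMES)

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(InputError):
            FeatureVector(values=(0.0,) * 76)


class TestSequenceFeatures:
    def test_uniform_composition(self):
        out = sequence_features("ACGU")
        for b in "ACGU":
            assert out[f"nt_proportion_{b}"] == 0.25
        assert out["gc_content"] == 0.5
        assert out["sequence_length"] == 4.0

    def test_gc_ratio(self):
        out = sequence_features("GGC")
        assert out["gc_content"] == 1.0
        assert out["gc_ratio"] == 2.0

    def test_single_dinucleotide_kind(self):
        out = sequence_features("AAA")
        assert out["dinucleotide_proportion_AA"] == 1.0
        others = [v for k, v in out.items()
                  if k.startswith("dinucleotide_proportion_") and k != "dinucleotide_proportion_AA"]
        assert all(v == 0.0 for v in others)

    def test_gc_ratio_guard_without_c(self):
        assert sequence_features("GGAA")["gc_ratio"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            sequence_features("")


class TestStructureFeatures:
    def test_simple_gc_hairpin(self):
        h = build_hairpin("GGGGAAAACCCC", "((((....))))")
        out = structure_features(h, compute_stem_stats(h))
        assert out["dP"] == pytest.approx(4 / 12)
        assert out["bp_proportion_AU"] == 0.0
        assert out["bp_proportion_GC"] == pytest.approx(4 / 12)
        assert out["bp_proportion_GU"] == 0.0
        assert out["bp_proportion_stem_GC"] == 1.0

    def test_unpaired_degenerate(self):
        h = build_hairpin("AAAAA", ".....")
        out = structure_features(h, compute_stem_stats(h))
        assert out["dP"] == 0.0
        assert all(out[f"bp_proportion_{c}"] == 0.0 for c in ("AU", "GC", "GU"))
        assert all(out[f"bp_proportion_stem_{c}"] == 0.0 for c in ("AU", "GC", "GU"))

    def test_two_stem_average(self):
        h = build_hairpin(seq_for_dotbracket("(((..((....))..)))"), "(((..((....))..)))")
        stats = compute_stem_stats(h)
        out = structure_features(h, stats)
        assert out["avg_bp_stem"] == pytest.approx(2 * stats.bp_number / stats.stem_number)


class TestTripletFeatures:
    def test_unpaired_uniform(self):
        h = build_hairpin("AAAA", "....")
        out = triplet_features(h)
        assert out["triplets_0"] == 1.0  # (A, "...") bin
        assert sum(out.values()) == pytest.approx(1.0)

    def test_hand_tally_on_small_hairpin(self):
        h = build_hairpin("GGGAAACCC", "(((...)))")
        out = triplet_features(h)
        # windows at i=1..7: nucleotide and (paired(i-1), paired(i), paired(i+1))
        # i=1 G ((( ; i=2 G ((. ; i=3 A (.. ; i=4 A ... ; i=5 A ..( ;
        # i=6 C .(( ; i=7 C (((
        expected = {
            ("G", "((("): 1 / 7, ("G", "((."): 1 / 7, ("A", "(.."): 1 / 7,
            ("A", "..."): 1 / 7, ("A", "..("): 1 / 7, ("C", ".(("): 1 / 7,
            ("C", "((("): 1 / 7,
        }
        patterns = ("...", "..(", ".(.", ".((", "(..", "(.(", "((.", "(((")
        for (nt, pat), frac in expected.items():
            idx = 8 * "ACGU".index(nt) + patterns.index(pat)
            assert out[f"triplets_{idx}"] == pytest.approx(frac)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_short_sequence_warns_all_zero(self):
        h = build_hairpin("AC", "..")
        out = triplet_features(h)
        assert all(v == 0.0 for v in out.values())


class TestThermoFeatures:
    def stats_of(self, db):
        h = build_hairpin(seq_for_dotbracket(db), db)
        return h, compute_stem_stats(h)

    def empty_ensemble(self, n):
        return EnsembleData(efe=0.0, mfe_frequency=1.0, diversity=0.0,
                            pair_prob=np.zeros((n, n)))

    def test_dg_direct_division(self):
        h, stats = self.stats_of("(" * 10 + "...." + ")" * 10)
        out = thermo_features(-30.0, self.empty_ensemble(24), stats, 60, 50.0)
        assert out["dG"] == pytest.approx(-0.5)

    def test_mfei1_direct_division(self):
        h, stats = self.stats_of("(" * 10 + "...." + ")" * 10)
        out = thermo_features(-30.0, self.empty_ensemble(24), stats, 60, 50.0)
        assert out["MFEI_1"] == pytest.approx(-0.6)

    def test_dq_closed_forms(self):
        stats = compute_stem_stats(build_hairpin("GGGGAAAACCCC", "((((....))))"))
        P = np.zeros((10, 10))
        P[0, 1] = P[1, 0] = 1.0
        out = thermo_features(-1.0, EnsembleData(0, 1, 0, P), stats, 10, 50.0)
        assert out["dQ"] == 0.0  # 1 * log2(1) == 0
        P = np.zeros((10, 10))
        P[0, 1] = P[1, 0] = 0.5
        out = thermo_features(-1.0, EnsembleData(0, 1, 0, P), stats, 10, 50.0)
        assert out["dQ"] == pytest.approx(-0.05)

    def test_division_guards(self):
        h = build_hairpin("AAAAA", ".....")
        stats = compute_stem_stats(h)
        out = thermo_features(0.0, self.empty_ensemble(5), stats, 5, 0.0)
        assert out["MFEI_1"] == 0.0
        assert out["MFEI_2"] == 0.0
        assert out["MFEI_4"] == 0.0


class TestComputeFeatures:
    def test_returns_exactly_77_named_values(self):
        h = folded_hairpin("GGGGGGAAAACCCCCC")
        fv = compute_features(h, fold_ensemble(h.sequence))
        assert len(fv) == 77
        assert set(fv.as_dict()) == set(FEATURE_NAMES)

    def test_deterministic(self):
        h = folded_hairpin("GGGGGGAAAACCCCCC")
        ens = fold_ensemble(h.sequence)
        assert compute_features(h, ens).values == compute_features(h, ens).values

    def test_hand_built_gc_hairpin_every_group(self):
        seq = "GGGGAAAACCCC"
        h = folded_hairpin(seq)
        assert h.structure.dotbracket == "((((....))))"
        ens = fold_ensemble(seq)
        fv = compute_features(h, ens)
        assert fv["sequence_length"] == 12.0
        assert fv["gc_content"] == pytest.approx(8 / 12)
        assert fv["gc_ratio"] == pytest.approx(1.0)
        assert fv["bp_number"] == 4.0
        assert fv["stem_number"] == 1.0
        assert fv["longest_stem_length"] == 4.0
        assert fv["terminal_loop_length"] == 4.0
        assert fv["dP"] == pytest.approx(4 / 12)
        assert fv["MFE"] == -12.0
        assert fv["EFE"] == pytest.approx(ens.efe)
        assert fv["dG"] == pytest.approx(-1.0)
        assert fv["MFEI_1"] == pytest.approx(-12.0 / (100 * 8 / 12))
        assert fv["MFEI_2"] == pytest.approx(-1.0 / 1)
        assert fv["MFEI_4"] == pytest.approx(-3.0)
        assert fv["mfe_efe_difference"] == pytest.approx(abs(-12.0 - ens.efe) / 12)

    def test_composition_scale_invariance(self):
        """Doubling arms with the same composition leaves composition features fixed."""
        h1 = folded_hairpin("GGGGAAAACCCC")
        h2 = folded_hairpin("GGGGGGGGAAAACCCCCCCC")
        f1 = compute_features(h1, fold_ensemble(h1.sequence))
        f2 = compute_features(h2, fold_ensemble(h2.sequence))
        assert f1["gc_ratio"] == pytest.approx(f2["gc_ratio"])
        assert f1["bp_proportion_stem_GC"] == f2["bp_proportion_stem_GC"] == 1.0


class TestCsvRoundTrip:
    def rows(self, rng, n):
        out = []
        for k in range(n):
            seq = "GG" + random_rna(rng, 20) + "AAAA" + random_rna(rng, 20) + "CC"
            h = folded_hairpin(seq, start=100 * k)
            out.append((h, compute_features(h, fold_ensemble(seq))))
        return out

    def test_shape(self, tmp_path, rng):
        path = tmp_path / "f.csv"
        write_feature_csv(self.rows(rng, 3), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4
        df = read_feature_csv(path)
        assert df.shape[0] == 3
        assert list(df.columns[-77:]) == list(FEATURE_NAMES)

    def test_values_survive_round_trip(self, tmp_path, rng):
        rows = self.rows(rng, 5)
        path = tmp_path / "f.csv"
        write_feature_csv(rows, path)
        df = read_feature_csv(path)
        for (h, fv), (_, rec) in zip(rows, df.iterrows()):
            for name in FEATURE_NAMES:
                assert rec[name] == pytest.approx(fv[name], abs=1e-12)

    def test_empty_gives_header_only(self, tmp_path):
        path = tmp_path / "f.csv"
        write_feature_csv([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1


class TestProportionInvariants:
    def test_groups_sum_to_one_and_signs(self, rng):
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(20, 120)))
            h = folded_hairpin(seq)
            fv = compute_features(h, fold_ensemble(seq))
            d = fv.as_dict()
            assert sum(d[f"nt_proportion_{b}"] for b in "ACGU") == pytest.approx(1.0, abs=1e-9)
            assert sum(v for k, v in d.items()
                       if k.startswith("dinucleotide_proportion_")) == pytest.approx(1.0, abs=1e-9)
            assert sum(d[f"triplets_{i}"] for i in range(32)) == pytest.approx(1.0, abs=1e-9)
            assert d["dQ"] <= 1e-12
            assert d["dG"] <= 1e-12
            assert d["MFE"] <= 1e-12
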