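import itertools

import numpy as np
import pandas as pd
import pytest

from hybridity.classifier import (
    NON_ADDITIVE_MODES,
    ContrastEvidence,
    classify_all,
    classify_gene,
    compile_de_gene_list,
)
from hybridity.data_model import ValidationError
from hybridity.pipeline import run_de_suite


def make_contrasts(fl=(False, 1.0), fx=(False, 1.0), lx=(False, 1.0), mx=(False, 1.0),
                   untestable=False):
    return {
        "F_vs_L": ContrastEvidence(*fl, untestable),
        "F_vs_Cross": ContrastEvidence(*fx),
        "L_vs_Cross": ContrastEvidence(*lx),
        "MPV_vs_Cross": ContrastEvidence(*mx),
    }


def enumeration_oracle(fx_de, fx_up, lx_de, lx_up, mx_de, f_is_high):
    """Independent rule table: expected (mode, sub_mode) for a configuration.

    Written directly from the scientific definitions: non-additivity needs
    the Cross to differ from the mid-parent; over-dominance means the Cross
    exceeds the HIGH parent significantly; under-dominance means it falls
    below the LOW parent; dominance means the Cross tracks exactly one
    parent; enhancing dominance means the tracked parent is the high one.
    """
    if not mx_de:
        return ("additive", "none")
    if f_is_high:
        high_de, high_up = fx_de, fx_up
        low_de, low_up = lx_de, lx_up
    else:
        high_de, high_up = lx_de, lx_up
        low_de, low_up = fx_de, fx_up
    if high_de and high_up:
        return ("over_dominance", "none")
    if low_de and not low_up:
        return ("under_dominance", "none")
    similar_to_f, similar_to_l = not fx_de, not lx_de
    if similar_to_f and not similar_to_l:
        return ("dominance_F", "enhancing" if f_is_high else "suppressing")
    if similar_to_l and not similar_to_f:
        return ("dominance_L", "suppressing" if f_is_high else "enhancing")
    return ("non_additive_unresolved", "none")


class TestClassifyGene:
    def test_additive_gate_ignores_other_contrasts(self):
        c = make_contrasts(fx=(True, 2.0), lx=(True, -2.0), mx=(False, 0.1))
        call = classify_gene("g", c, 100, 20, 60)
        assert call.mode == "additive"

    def test_over_dominance_above_high_parent(self):
        # mF=100 is the high parent; Cross significantly above it
        c = make_contrasts(fx=(True, 1.5), lx=(True, 3.0), mx=(True, 2.0))
        call = classify_gene("g", c, 100, 20, 300)
        assert call.mode == "over_dominance"

    def test_under_dominance_below_low_parent(self):
        c = make_contrasts(fx=(True, -3.0), lx=(True, -1.5), mx=(True, -2.0))
        call = classify_gene("g", c, 100, 20, 5)
        assert call.mode == "under_dominance"

    def test_dominance_f_enhancing(self):
        # similar to F (high parent), different from L
        c = make_contrasts(fx=(False, 0.1), lx=(True, 2.0), mx=(True, 1.2))
        call = classify_gene("g", c, 100, 20, 95)
        assert (call.mode, call.sub_mode) == ("dominance_F", "enhancing")

    def test_de_vs_both_parents_between_them_is_unresolved(self):
        # Cross strictly between the parents but DE from both and from MPV
        c = make_contrasts(fx=(True, -1.2), lx=(True, 1.2), mx=(True, 1.1))
        call = classify_gene("g", c, 100, 20, 50)
        assert call.mode == "non_additive_unresolved"

    def test_untestable_contrast_dominates(self):
        c = make_contrasts(mx=(True, 2.0), untestable=True)
        assert classify_gene("g", c, 1, 1, 1).mode == "untestable"

    def test_missing_contrast_named_in_error(self):
        c = make_contrasts()
        del c["L_vs_Cross"]
        with pytest.raises(ValidationError, match="L_vs_Cross"):
            classify_gene("g", c, 1, 1, 1)

    def test_exhaustive_truth_table_equivalence(self):
        """classify_gene agrees with the enumeration oracle on every
        DE-flag / direction / mean-order configuration."""
        flags = [True, False]
        for fx_de, fx_up, lx_de, lx_up, mx_de, mx_up, fl_de, f_is_high in itertools.product(
            flags, repeat=8
        ):
            mf, ml = (100.0, 20.0) if f_is_high else (20.0, 100.0)
            c = make_contrasts(
                fl=(fl_de, 2.0),
                fx=(fx_de, 1.5 if fx_up else -1.5),
                lx=(lx_de, 1.5 if lx_up else -1.5),
                mx=(mx_de, 1.5 if mx_up else -1.5),
            )
            call = classify_gene("g", c, mf, ml, 60.0)
            expected = enumeration_oracle(fx_de, fx_up, lx_de, lx_up, mx_de, f_is_high)
            assert (call.mode, call.sub_mode) == expected, (
                f"config fx=({fx_de},{fx_up}) lx=({lx_de},{lx_up}) "
                f"mx={mx_de} f_high={f_is_high}"
            )


class TestCompileDeGeneList:
    def _tables(self, de_sets):
        genes = [f"g{i}" for i in range(20)]
        out = {}
        for name, de in de_sets.items():
            out[name] = pd.DataFrame(
                {"is_de": [g in de for g in genes], "log2fc": 0.0, "untestable": False},
                index=genes,
            )
        return out

    def test_disjoint_sets_union(self):
        t = self._tables(
            {
                "F_vs_L": {"g0", "g1", "g2"},
                "F_vs_Cross": {"g3", "g4"},
                "L_vs_Cross": {"g5"},
                "MPV_vs_Cross": {"g6"},
            }
        )
        assert len(compile_de_gene_list(t)) == 7

    def test_identical_sets_idempotent(self):
        s = {"g0", "g1"}
        t = self._tables({k: s for k in ("F_vs_L", "F_vs_Cross", "L_vs_Cross", "MPV_vs_Cross")})
        assert compile_de_gene_list(t) == s

    def test_reciprocal_contrast_excluded(self):
        t = self._tables(
            {
                "F_vs_L": {"g0"},
                "F_vs_Cross": set(),
                "L_vs_Cross": set(),
                "MPV_vs_Cross": set(),
                "FL_vs_LF": {"g9"},
            }
        )
        assert compile_de_gene_list(t) == {"g0"}

    def test_random_sets_match_brute_force_union(self):
        rng = np.random.default_rng(5)
        names = ("F_vs_L", "F_vs_Cross", "L_vs_Cross", "MPV_vs_Cross")
        sets = {
            n: set(rng.choice([f"g{i}" for i in range(20)], size=rng.integers(0, 15),
                              replace=False))
            for n in names
        }
        brute = set()
        for n in names:
            for g in sets[n]:
                if g not in brute:
                    brute.add(g)
        assert compile_de_gene_list(self._tables(sets)) == brute


class TestClassifyAll:
    def test_modes_partition_all_genes(self, balanced_suite):
        cm, truth, suite = balanced_suite
        calls, summary = classify_all(
            {k: v for k, v in suite.contrasts.items() if k != "FL_vs_LF"},
            suite.normalized,
            suite.groups,
        )
        assert len(calls) == len(cm.gene_ids)
        assert summary["n"].sum() == len(cm.gene_ids)
        assert calls["mode"].isin(
            NON_ADDITIVE_MODES + ("additive", "untestable")
        ).all()
        # sub-modes appear exactly on dominance calls
        has_sub = calls["sub_mode"] != "none"
        assert (calls.loc[has_sub, "mode"].isin(["dominance_F", "dominance_L"])).all()
        assert (calls.loc[calls["mode"].isin(["dominance_F", "dominance_L"]), "sub_mode"]
                != "none").all()

    def test_all_null_simulation_is_almost_all_additive(self):
        from hybridity.synthetic import SimConfig, simulate_counts

        cfg = SimConfig(n_genes=400, mode_proportions={"null": 1.0}, seed=19)
        cm, _ = simulate_counts(cfg)
        suite = run_de_suite(cm, mpv_seed=19)
        calls, _ = classify_all(
            {k: v for k, v in suite.contrasts.items() if k != "FL_vs_LF"},
            suite.normalized,
            suite.groups,
        )
        testable = calls[calls["mode"] != "untestable"]
        assert (testable["mode"] == "additive").mean() >= 0.99

    def test_tightening_lfc_only_moves_genes_toward_additive(self, balanced_sim):
        cfg, cm, truth = balanced_sim
        non_add = {}
        for lfc_min in (1.0, 1.5):
            suite = run_de_suite(cm, lfc_min=lfc_min, mpv_seed=11)
            calls, _ = classify_all(
                {k: v for k, v in suite.contrasts.items() if k != "FL_vs_LF"},
                suite.normalized,
                suite.groups,
            )
            non_add[lfc_min] = set(calls.index[calls["mode"].isin(NON_ADDITIVE_MODES)])
        assert non_add[1.5] <= non_add[1.0]
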