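"""Differential expression, FDR, set algebra and splicing-index behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hyposcape import synthetic
from hyposcape.config import SimulationConfig
from hyposcape.errors import ConfigurationError, DomainError
from hyposcape.expression import (
    bh_fdr,
    call_splicing,
    deg_set_algebra,
    moderated_de_test,
    select_event,
    signed_fold_change,
    splicing_index,
)


def _bh_oracle(p):
    """Textbook step-up: sort, multiply by m/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "case, control, expected", [(4, 2, 2.0), (2, 4, -2.0), (3, 3, 1.0)]
    )
    def test_closed_forms(self, case, control, expected):
        assert signed_fold_change(case, control) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_antisymmetry(self, a, b):
        if abs(a / b - 1) < 1e-9:
            return
        assert signed_fold_change(a, b) == pytest.approx(
            -signed_fold_change(b, a), rel=1e-9
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            signed_fold_change(0.0, 1.0)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_p_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_single_p_identity(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @pytest.mark.parametrize("bad", [[], [1.5], [-0.1]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(DomainError):
            bh_fdr(bad)


def _matrix(values, n1, n2):
    values = np.atleast_2d(values)
    cols = [f"H{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
    conditions = {c: ("hypoxia" if c.startswith("H") else "normoxia") for c in cols}
    return (
        pd.DataFrame(values, columns=cols, index=[f"t{i}" for i in range(len(values))]),
        conditions,
    )


class TestModeratedDeTest:
    def test_flat_transcript_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(6, 0.2, size=(50, 8))
        base[0] = 100.0  # identical in both groups
        matrix, cond = _matrix(base, 4, 4)
        results = moderated_de_test(matrix, cond)
        assert results[0].signed_fc == pytest.approx(1.0)
        assert not results[0].significant

    def test_prior_zero_reduces_to_classical_t(self):
        rng = np.random.default_rng(1)
        matrix, cond = _matrix(rng.lognormal(6, 0.5, size=(40, 10)), 5, 5)
        results = moderated_de_test(matrix, cond, prior_df=0.0)
        log2 = np.log2(matrix.to_numpy())
        ref = stats.ttest_ind(log2[:, :5], log2[:, 5:], axis=1)
        for r, p_ref in zip(results, ref.pvalue):
            assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_planted_effects_recovered(self):
        cfg = SimulationConfig(seed=21)
        matrix, sheet, truth = synthetic.simulate_expression_matrix(cfg)
        results = moderated_de_test(matrix, sheet)
        called = {r.transcript for r in results if r.significant}
        planted = set(truth["transcript"])
        sensitivity = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.1

    def test_small_group_rejected(self):
        matrix, cond = _matrix(np.full((3, 3), 5.0), 1, 2)
        with pytest.raises(DomainError):
            moderated_de_test(matrix, cond)


class TestDegSetAlgebra:
    def test_identical_sets(self):
        sets = {"a": {1, 2}, "b": {1, 2}, "c": {1, 2}}
        groups = {"a": "HH", "b": "HH", "c": "HL"}
        common, hh, hl = deg_set_algebra(sets, groups)
        assert (common, hh, hl) == ({1, 2}, set(), set())

    def test_worked_example(self):
        sets = {
            "a1": {1, 2, 3},
            "a2": {1, 2, 4},
            "a3": {1, 2, 5},
            "b1": {1, 6},
            "b2": {1, 7},
            "b3": {1, 8},
        }
        groups = {k: ("HH" if k.startswith("a") else "HL") for k in sets}
        common, hh, hl = deg_set_algebra(sets, groups)
        assert common == {1}
        assert hh == {2}
        assert hl == set()
        assert not (common & hh or common & hl or hh & hl)

    def test_disjoint_groups(self):
        sets = {"a": {1, 2}, "b": {3, 4}}
        groups = {"a": "HH", "b": "HL"}
        common, hh, hl = deg_set_algebra(sets, groups)
        assert common == set()
        assert hh == {1, 2}
        assert hl == {3, 4}

    def test_unknown_line_rejected(self):
        with pytest.raises(ConfigurationError):
            deg_set_algebra({"a": {1}, "b": {1}}, {"a": "HH"})


class TestSplicingIndex:
    def _inputs(self, probe_factor_case=1.0, gene_factor_case=1.0):
        rng = np.random.default_rng(0)
        samples = ["N1", "N2", "N3", "H1", "H2", "H3"]
        cond = {s: ("hypoxia" if s.startswith("H") else "normoxia") for s in samples}
        gene = pd.DataFrame(
            rng.lognormal(8, 0.01, size=(5, 6)),
            index=[f"t{i}" for i in range(5)],
            columns=samples,
        )
        probes = pd.DataFrame(
            0.4 * gene.loc[[f"t{i}" for i in range(5) for _ in (0, 1)]].to_numpy(),
            index=[f"t{i}_P{j}" for i in range(5) for j in (1, 2)],
            columns=samples,
        )
        hyp = ["H1", "H2", "H3"]
        gene.loc["t0", hyp] *= gene_factor_case
        # probes follow their gene; probe_factor_case is the shift relative to it
        probes.loc[["t0_P1", "t0_P2"], hyp] *= gene_factor_case
        probes.loc["t0_P1", hyp] *= probe_factor_case
        pmap = pd.DataFrame(
            {
                "probe_id": probes.index,
                "transcript": [p.rsplit("_", 1)[0] for p in probes.index],
            }
        )
        return probes, pmap, gene, cond

    def test_proportional_change_is_null(self):
        probes, pmap, gene, cond = self._inputs(gene_factor_case=2.0)
        si = splicing_index(probes, pmap, gene, cond)
        t0 = si.set_index("transcript").loc["t0"]
        # signed FC dialect: magnitude 1 means no change after normalization
        assert abs(t0["splicing_index"]) == pytest.approx(1.0, abs=0.05)

    def test_probe_only_shift_gives_si(self):
        probes, pmap, gene, cond = self._inputs(probe_factor_case=4.0)
        si = splicing_index(probes, pmap, gene, cond)
        t0 = si.set_index("transcript").loc["t0"]
        assert t0["splicing_index"] == pytest.approx(4.0, rel=0.05)
        assert t0["probe_id"] == "t0_P1"

    def test_scale_invariance_per_sample(self):
        probes, pmap, gene, cond = self._inputs(probe_factor_case=4.0)
        si_base = splicing_index(probes, pmap, gene, cond)
        scale = pd.Series(
            [3.0, 1.0, 0.5, 2.0, 1.0, 7.0], index=probes.columns
        )
        si_scaled = splicing_index(probes * scale, pmap, gene * scale, cond)
        np.testing.assert_allclose(
            si_base["splicing_index"], si_scaled["splicing_index"], rtol=1e-9
        )

    def test_probe_without_gene_signal(self):
        probes, pmap, gene, cond = self._inputs()
        with pytest.raises(DomainError):
            splicing_index(probes, pmap, gene.drop(index="t0"), cond)


class TestSelectEvent:
    def test_argmax(self):
        assert select_event([("cassette exon", 0.9), ("intron retention", 0.4)]) == (
            "cassette exon",
            0.9,
        )

    def test_empty_is_excluded(self):
        assert select_event([]) is None

    def test_tie_broken_by_label_order(self):
        assert select_event([("alt 3' acceptor", 0.5), ("alt 5' donor", 0.5)]) == (
            "alt 5' donor",
            0.5,
        )

    def test_score_out_of_range(self):
        with pytest.raises(DomainError):
            select_event([("complex", 1.2)])


class TestCallSplicing:
    def test_planted_cassette_exons_flagged(self):
        cfg = SimulationConfig(seed=13, n_transcripts=600)
        psr, pmap, gene, sheet, events, truth = synthetic.simulate_splicing_signals(cfg)
        results = call_splicing(psr, pmap, gene, sheet, events)
        reported = {r.transcript: r for r in results if r.significant and not r.excluded}
        planted = set(truth["transcript"])
        recovered = planted & set(reported)
        assert len(recovered) / len(planted) >= 0.8
        assert all(reported[t].event == "cassette exon" for t in recovered)

    def test_null_scenario_reports_nothing(self):
        cfg = SimulationConfig(seed=14, n_transcripts=600, splice_fraction=0.0)
        psr, pmap, gene, sheet, events, _ = synthetic.simulate_splicing_signals(cfg)
        results = call_splicing(psr, pmap, gene, sheet, events)
        assert not [r for r in results if r.significant and not r.excluded]
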