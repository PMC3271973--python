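"""The three-stage candidate cascade and its accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seroscreen import (
    ScreenParams,
    filter_expressed,
    intersect_secretome,
    retained_percentages,
    run_screen,
    variability_filter,
)
from conftest import make_matrix


def make_annotation(gene_ids, secreted_ids):
    return pd.DataFrame(
        {"length_bp": 1000, "secreted": [g in set(secreted_ids) for g in gene_ids]},
        index=pd.Index(gene_ids, name="gene_id"),
    )


class TestFilterExpressed:
    def test_mean_exactly_at_floor_is_excluded(self):
        m = make_matrix(np.array([[1.0, 1.0], [1.0, 1.5]]))
        assert filter_expressed(m, ScreenParams()) == {"G0001"}

    def test_all_zero_matrix_yields_empty_set(self):
        m = make_matrix(np.zeros((5, 3)))
        assert filter_expressed(m, ScreenParams()) == set()

    def test_count_matches_naive_loop(self, random_matrix):
        params = ScreenParams(min_mean_coverage=1.0)
        got = filter_expressed(random_matrix, params)
        expected = {
            g
            for g in random_matrix.values.index
            if random_matrix.values.loc[g].mean() > 1.0
        }
        assert got == expected


class TestIntersectSecretome:
    def test_empty_secretome_gives_empty_result(self):
        ann = make_annotation(["a", "b"], [])
        assert intersect_secretome({"a", "b"}, ann) == set()

    def test_gene_ids_are_case_sensitive(self):
        ann = make_annotation(["IGFBP4", "igfbp4"], ["IGFBP4"])
        assert intersect_secretome({"igfbp4"}, ann) == set()
        assert intersect_secretome({"IGFBP4"}, ann) == {"IGFBP4"}

    def test_known_overlap_by_construction(self, rng):
        genes = [f"g{i}" for i in range(1000)]
        secreted = set(rng.choice(genes, size=170, replace=False))
        ann = make_annotation(genes, secreted)
        assert intersect_secretome(set(genes), ann) == secreted


class TestVariabilityFilter:
    def test_zero_variance_gene_retained(self):
        m = make_matrix(np.array([[10.0, 10.0, 10.0]]))
        retained, disqualified = variability_filter(m, {"G0000"}, ScreenParams())
        assert retained == {"G0000"} and disqualified == set()

    def test_bursty_gene_disqualified(self):
        # mean 10, sd sqrt(300) ~ 17.3 > 7.5
        m = make_matrix(np.array([[0.0, 0.0, 30.0]]))
        retained, disqualified = variability_filter(m, {"G0000"}, ScreenParams())
        assert disqualified == {"G0000"}

    def test_zero_mean_gene_disqualified_by_convention(self):
        m = make_matrix(np.zeros((1, 4)))
        retained, disqualified = variability_filter(m, {"G0000"}, ScreenParams())
        assert disqualified == {"G0000"}

    def test_partition_of_input(self, random_matrix):
        genes = set(random_matrix.values.index[:50])
        retained, disqualified = variability_filter(random_matrix, genes, ScreenParams())
        assert retained | disqualified == genes
        assert retained & disqualified == set()

    def test_published_cascade_proportions(self):
        # 1169 of 1710 secreted candidates exceed the CV criterion by
        # construction; the survivors are 32% and the disqualified 68%
        n_keep, n_drop, n_samp = 541, 1169, 22
        vals = np.zeros((n_keep + n_drop, n_samp))
        vals[:n_keep, :] = 10.0  # sd 0 <= 7.5
        vals[n_keep:, 0] = 10.0 * n_samp  # single burst: sd >> 0.75 * mean
        m = make_matrix(vals)
        retained, disqualified = variability_filter(
            m, set(m.values.index), ScreenParams()
        )
        assert (len(retained), len(disqualified)) == (n_keep, n_drop)
        assert retained_percentages(len(retained), len(disqualified)) == (32, 68)


class TestRunScreen:
    def _flagship(self):
        """Deterministic matrix with construction-known stage counts."""
        n_samp = 22
        blocks = {
            "below_floor": (300, 0.5),  # mean 0.5, fails the floor
            "kept": (200, 10.0),  # expressed, secreted, sd 0
            "bursty": (120, None),  # expressed, secreted, high CV
            "nonsecreted": (380, 5.0),  # expressed, not secreted
        }
        rows, secreted = [], []
        gene_ids = []
        i = 0
        for name, (count, level) in blocks.items():
            for _ in range(count):
                gid = f"{name}_{i}"
                gene_ids.append(gid)
                if name == "bursty":
                    row = np.zeros(n_samp)
                    row[0] = 220.0
                else:
                    row = np.full(n_samp, level)
                rows.append(row)
                if name in ("kept", "bursty"):
                    secreted.append(gid)
                i += 1
        vals = np.asarray(rows)
        m = make_matrix(vals, {"T": n_samp})
        m.values.index = pd.Index(gene_ids, name="gene_id")
        ann = make_annotation(gene_ids, secreted)
        return m, ann

    def test_stage_counts_match_construction(self):
        m, ann = self._flagship()
        result = run_screen(m, ann)
        assert result.stage_counts == {
            "n_input": 1000,
            "n_expressed": 700,
            "n_secreted": 320,
            "n_disqualified": 120,
            "n_candidates": 200,
        }
        assert len(result.candidates) == 200

    def test_accounting_identity(self):
        m, ann = self._flagship()
        c = run_screen(m, ann).stage_counts
        assert c["n_secreted"] == c["n_disqualified"] + c["n_candidates"]

    def test_infinite_cv_threshold_disqualifies_nothing(self):
        m, ann = self._flagship()
        result = run_screen(m, ann, ScreenParams(cv_threshold=np.inf))
        assert result.stage_counts["n_disqualified"] == 0

    def test_candidates_equal_stagewise_set_intersection(self, random_matrix):
        params = ScreenParams()
        genes = list(random_matrix.values.index)
        ann = make_annotation(genes, genes[::3])
        result = run_screen(random_matrix, ann, params)
        expressed = filter_expressed(random_matrix, params)
        secreted = intersect_secretome(set(genes), ann)
        retained, _ = variability_filter(random_matrix, set(genes), params)
        assert set(result.candidates) == expressed & secreted & retained

    def test_candidates_ranked_by_mean_descending(self, random_matrix):
        genes = list(random_matrix.values.index)
        ann = make_annotation(genes, genes)
        result = run_screen(random_matrix, ann)
        means = [random_matrix.values.loc[g].mean() for g in result.candidates]
        assert all(a >= b for a, b in zip(means, means[1:]))

    @given(cv_lo=st.floats(0.2, 0.7), cv_hi_delta=st.floats(0.01, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_cv_threshold_never_shrinks_retained(self, cv_lo, cv_hi_delta):
        rng = np.random.default_rng(11)
        vals = rng.lognormal(1.0, 1.0, size=(60, 6))
        m = make_matrix(vals)
        genes = set(m.values.index)
        low, _ = variability_filter(m, genes, ScreenParams(cv_threshold=cv_lo))
        high, _ = variability_filter(
            m, genes, ScreenParams(cv_threshold=cv_lo + cv_hi_delta)
        )
        assert low <= high

    @given(floor_lo=st.floats(0.0, 3.0), delta=st.floats(0.01, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_floor_never_grows_expressed(self, floor_lo, delta):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(0.5, 1.2, size=(60, 6))
        m = make_matrix(vals)
        low = filter_expressed(m, ScreenParams(min_mean_coverage=floor_lo))
        high = filter_expressed(m, ScreenParams(min_mean_coverage=floor_lo + delta))
        assert high <= low
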