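"""Dynamic network mechanism analysis: selection, clustering, scoring, overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from sympy import Rational, binomial

from genesetdyn import (
    DNMConfig,
    NormalizedProfile,
    ValidationError,
    cluster_modules,
    critical_correlation,
    identify_critical_group,
    overlap_pvalue,
    score_module,
    select_control_sets,
    select_high_variance_sets,
)


def overlap_oracle(A, B, C, N, n):
    """Independent exact-rational transcription of the three-set overlap sum."""
    total = Rational(0)
    for k in range(n + 1):
        t1 = binomial(A, k) * binomial(N - A, B - k) / binomial(N, B)
        t2 = (
            binomial(A + B - 2 * k, n - k)
            * binomial(N - A - B + 2 * k, C - n + k)
            / binomial(N, C)
        )
        total += t1 * t2
    return total


def _profile(mat, group_labels, sets=None):
    mat = np.asarray(mat, dtype=float)
    sets = sets or [f"S{i:02d}" for i in range(mat.shape[0])]
    samples = [f"p{i:03d}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=pd.Index(sets, name="gene_set"), columns=samples)
    group = pd.Series(group_labels, index=df.columns, name="group")
    return NormalizedProfile(df, group=group)


class TestHighVarianceSelection:
    def test_ceiling_cut_and_descending_sd(self, rng):
        mat = rng.standard_normal((100, 10)) * np.linspace(1, 3, 100)[:, None]
        prof = _profile(mat, ["g"] * 10)
        names = select_high_variance_sets(prof, "g", 0.05)
        assert len(names) == 5  # ceil(0.05 * 100)
        sds = prof.values.std(axis=1, ddof=1)
        assert list(names) == list(sds.sort_values(ascending=False).index[:5])

    def test_ceiling_rounds_up(self, rng):
        prof = _profile(rng.standard_normal((41, 6)), ["g"] * 6)
        assert len(select_high_variance_sets(prof, "g", 0.05)) == 3  # ceil(2.05)

    def test_equal_sds_tie_break_by_name(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        mat = np.repeat(base, 6, axis=0)
        prof = _profile(mat, ["g"] * 4, sets=["Sf", "Sa", "Sd", "Sb", "Se", "Sc"])
        names = select_high_variance_sets(prof, "g", 0.5)
        assert names == ["Sa", "Sb", "Sc"]

    def test_too_few_samples_rejected(self, rng):
        prof = _profile(rng.standard_normal((10, 4)), ["g", "g", "h", "h"])
        with pytest.raises(ValidationError):
            select_high_variance_sets(prof, "g", 0.05)


class TestClusterModules:
    def test_critical_correlation_matches_t_inversion(self):
        # df = 18, two-sided p = 0.01 -> t = 2.878, r = t/sqrt(df + t^2)
        assert critical_correlation(20, 0.01) == pytest.approx(0.5614, abs=5e-4)

    def test_identical_vectors_cluster_together(self, rng):
        v = rng.standard_normal(12)
        mat = np.vstack([v, v, rng.standard_normal(12)])
        prof = _profile(mat, ["g"] * 12, sets=["A", "B", "Z"])
        modules = cluster_modules(prof, "g", ["A", "B", "Z"], 0.01)
        assert ("A", "B") in modules

    def test_null_false_positive_pairs_controlled_at_nominal_rate(self):
        """Independent noise vectors: co-clustered pairs stay near the
        per-pair significance level, and none form under a stringent one.

        With 50 candidates and module_p = 0.01 about 1225 * 0.01 = 12 pairs
        per run are expected significant by chance, so some two-member
        module almost always forms; the controlled quantity is the number
        of intra-module pairs, bounded by the significant-pair count.
        """
        runs = 40
        pair_counts = []
        stringent_hits = 0
        for seed in range(runs):
            r = np.random.default_rng(seed)
            prof = _profile(r.standard_normal((50, 20)), ["g"] * 20)
            modules = cluster_modules(prof, "g", list(prof.sets), 0.01)
            pair_counts.append(
                sum(len(m) * (len(m) - 1) // 2 for m in modules)
            )
            if cluster_modules(prof, "g", list(prof.sets), 1e-5):
                stringent_hits += 1
        expected = 0.01 * math.comb(50, 2)
        # complete linkage only co-clusters significant pairs, so the mean
        # cannot exceed the expected significant-pair count by much
        assert np.mean(pair_counts) <= expected + 3 * np.std(pair_counts) / math.sqrt(runs)
        assert stringent_hits / runs <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / runs)

    def test_intra_module_pairs_exceed_critical_correlation(self, rng):
        """Complete-linkage cut guarantees every member pair is significant."""
        m = 16
        shared = rng.standard_normal(m)
        mat = np.vstack(
            [0.9 * shared + 0.4 * rng.standard_normal(m) for _ in range(4)]
            + [rng.standard_normal(m) for _ in range(8)]
        )
        prof = _profile(mat, ["g"] * m)
        r_crit = critical_correlation(m, 0.01)
        for members in cluster_modules(prof, "g", list(prof.sets), 0.01):
            sub = prof.values.loc[list(members)].to_numpy()
            corr = np.corrcoef(sub)
            iu = np.triu_indices(len(members), k=1)
            assert corr[iu].min() >= r_crit - 1e-12

    def test_too_few_samples_rejected(self, rng):
        prof = _profile(rng.standard_normal((5, 3)), ["g"] * 3)
        with pytest.raises(ValidationError):
            cluster_modules(prof, "g", list(prof.sets), 0.01)


class TestControlSelection:
    def test_cardinality_and_disjointness(self, rng):
        prof = _profile(rng.standard_normal((12, 10)), ["ctl"] * 10)
        members = ("S00", "S01")
        controls = select_control_sets(prof, members, "ctl", 5)
        assert len(controls) == 5
        assert not set(controls) & set(members)

    def test_duplicate_of_member_ranks_first(self, rng):
        m = 10
        mat = rng.standard_normal((6, m))
        mat[4] = mat[0]  # S04 duplicates member S00 in the control group
        prof = _profile(mat, ["ctl"] * m)
        controls = select_control_sets(prof, ("S00", "S01"), "ctl", 3)
        assert controls[0] == "S04"

    def test_small_pool_returns_entire_pool(self, rng):
        prof = _profile(rng.standard_normal((4, 8)), ["ctl"] * 8)
        controls = select_control_sets(prof, ("S00", "S01"), "ctl", 10)
        assert set(controls) == {"S02", "S03"}


class TestScoreModule:
    def test_combined_score_arithmetic(self, rng):
        """S = SD * PCC_in / PCC_out on a constructed two-member module."""
        m = 200000
        r = np.random.default_rng(1)
        shared = r.standard_normal(m)
        a = shared
        b = 0.99 * shared + np.sqrt(1 - 0.99**2) * r.standard_normal(m)
        c = r.standard_normal(m)
        prof = _profile(np.vstack([a, b, c]), ["g"] * m, sets=["A", "B", "Z"])
        mod = score_module(prof, ("A", "B"), ("Z",), "g")
        assert mod.score == pytest.approx(mod.sd_mean * mod.pcc_in / mod.pcc_out)
        assert mod.pcc_in == pytest.approx(0.99, abs=0.01)

    def test_scale_equivariance(self, rng):
        mat = rng.standard_normal((5, 15))
        prof = _profile(mat, ["g"] * 15)
        doubled = _profile(mat * 2.0, ["g"] * 15)
        m1 = score_module(prof, ("S00", "S01"), ("S02",), "g")
        m2 = score_module(doubled, ("S00", "S01"), ("S02",), "g")
        assert m2.sd_mean == pytest.approx(2 * m1.sd_mean)
        assert m2.pcc_in == pytest.approx(m1.pcc_in)
        assert m2.score == pytest.approx(2 * m1.score)

    def test_planted_module_outscores_random_one(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = 25
            shared = r.standard_normal(m)
            planted = np.vstack(
                [2.0 * (0.9 * shared + 0.45 * r.standard_normal(m)) for _ in range(3)]
            )
            noise = r.standard_normal((6, m))
            prof = _profile(np.vstack([planted, noise]), ["g"] * m)
            ctl = ("S06", "S07", "S08")
            planted_score = score_module(prof, ("S00", "S01", "S02"), ctl, "g").score
            random_score = score_module(prof, ("S03", "S04", "S05"), ctl, "g").score
            wins += planted_score > random_score
        assert wins >= 18

    def test_pcc_out_floor_flagged(self, rng):
        m = 12
        mat = rng.standard_normal((3, m))
        mat[2] = 0.0  # constant control vector -> undefined PCC -> floored path
        mat[2, 0] = 1e-15
        prof = _profile(mat, ["g"] * m)
        mod = score_module(prof, ("S00", "S01"), ("S02",), "g")
        assert np.isfinite(mod.score)


class TestIdentifyCriticalGroup:
    def _planted_profile(self, seed=0):
        from genesetdyn import FixtureSpec, ScoringConfig, score_dataset, z_normalize
        from genesetdyn.fixtures import generate_multigroup_dataset

        spec = FixtureSpec(seed=seed)
        expr, coll = generate_multigroup_dataset(spec)
        return z_normalize(score_dataset(expr, coll, ScoringConfig())), spec

    def test_recovers_planted_group_and_module(self):
        prof, spec = self._planted_profile(41)
        result = identify_critical_group(prof, DNMConfig(control_group="HSC+"))
        assert result.found
        assert result.critical_group == spec.module_group
        assert set(result.winning_module.members) == set(spec.module_sets)

    def test_duplicated_groups_tie_flagged_lowest_label_wins(self, rng):
        mat = rng.standard_normal((40, 8))
        shared = rng.standard_normal(8)
        mat[:3] = 2.0 * shared + 0.1 * rng.standard_normal((3, 8))
        both = np.hstack([mat, mat])
        prof = _profile(both, ["a"] * 8 + ["b"] * 8)
        result = identify_critical_group(
            prof, DNMConfig(control_group="a", sd_quantile=0.1)
        )
        assert result.found and result.tied
        assert result.critical_group == "a"

    def test_no_module_flagged(self, rng):
        prof = _profile(rng.standard_normal((60, 20)), (["a"] * 10 + ["b"] * 10))
        config = DNMConfig(control_group="a", module_p=1e-9)
        result = identify_critical_group(prof, config)
        if not result.found:
            assert result.critical_group is None

    def test_single_group_rejected(self, rng):
        prof = _profile(rng.standard_normal((10, 6)), ["a"] * 6)
        with pytest.raises(ValidationError):
            identify_critical_group(prof, DNMConfig(control_group="a"))


class TestOverlapPvalue:
    def test_degenerate_full_overlap_is_one(self):
        assert overlap_pvalue(10, 10, 10, 10, 10) == pytest.approx(1.0, abs=0)

    def test_matches_exact_rational_oracle_on_grid(self):
        for A in (1, 3, 8, 30):
            for B in (2, 8, 30):
                for C in (1, 8, 30):
                    for N in (30, 67, 200):
                        for n in (0, 1, 4, 10):
                            got = overlap_pvalue(A, B, C, N, n)
                            want = float(overlap_oracle(A, B, C, N, n))
                            assert got == pytest.approx(want, abs=1e-12), (A, B, C, N, n)

    def test_values_are_probabilities_summing_to_at_most_one(self):
        total = sum(overlap_pvalue(6, 7, 5, 40, n) for n in range(13))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_tail_decreasing_past_mean_overlap(self):
        vals = [overlap_pvalue(10, 10, 10, 50, n) for n in range(11)]
        peak = int(np.argmax(vals))
        assert all(vals[i] >= vals[i + 1] for i in range(peak, 10))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            overlap_pvalue(11, 5, 5, 10, 0)
        with pytest.raises(ValidationError):
            overlap_pvalue(5, 5, 5, 10, -1)
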