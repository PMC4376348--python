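"""Reproducible study harnesses over the full pipeline.

Each function here runs one of the package's headline experiments end to end
— scorer calibration and power, planted-module recovery by the dynamic
network mechanism analysis, and survival-indicator recovery and null
calibration — at problem sizes small enough for routine re-execution on a
single CPU, and returns plain dictionaries of summary numbers.  The same
entry points back both the test suite and the reproduction script, so the
numbers those two report are computed by identical code paths.

All randomness flows from a single integer seed per study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .dnm import DNMConfig, identify_critical_group
from .faime import ScoringConfig, faime_scorer, score_dataset
from .fixtures import FixtureSpec, generate_multigroup_dataset, generate_survival_cohort
from .normalize import z_normalize
from .rxa import (
    compute_indicator,
    empirical_pvalue,
    logrank_two_group,
    stratify_and_test,
    train_indicator_weights,
)
from .simulate import SimulationConfig, evaluate_scorer

#: scaled-down replicate counts for routine runs; the full study design uses
#: p = 5000 genes and 1000 replicates
TYPE1_CONFIG = dict(p=2000, n_per_group=20, set_size=30, de_fraction=0.8, effect=0.0)
POWER_CONFIGS = {
    "n10_m05": dict(n_per_group=10, effect=0.5),
    "n10_m1": dict(n_per_group=10, effect=1.0),
    "n40_m05": dict(n_per_group=40, effect=0.5),
    "n40_m1": dict(n_per_group=40, effect=1.0),
}


def type1_study(alphas=(1.0, 5.0, 10.0), reps: int = 200, seed: int = 0) -> dict[str, float]:
    """Type-I error of FAIME.alpha scorers under the null (effect m = 0)."""
    out = {}
    for alpha in alphas:
        config = SimulationConfig(**TYPE1_CONFIG, reps=reps, seed=seed)
        result = evaluate_scorer(config, faime_scorer(alpha))
        out[f"type1_faime{alpha:g}"] = result.type1
    return out


def power_study(alpha: float = 5.0, reps: int = 500, seed: int = 0) -> dict[str, float]:
    """Power of FAIME.alpha across sample-size and effect-size conditions.

    Planted DE set of 30 genes, DE fraction 0.8, p = 2000 genes; power is
    expected non-decreasing from n = 10 to n = 40 per group (at m = 1) and
    from m = 0.5 to m = 1 (at n = 40).
    """
    out = {}
    for name, overrides in POWER_CONFIGS.items():
        config = SimulationConfig(
            **{**TYPE1_CONFIG, **overrides}, reps=reps, seed=seed
        )
        result = evaluate_scorer(config, faime_scorer(alpha))
        out[f"power_{name}"] = result.power
    return out


def _module_min_pcc(profile, module) -> float:
    cols = profile.samples[(profile.group == module.group).to_numpy()]
    sub = profile.values.loc[list(module.members), cols].to_numpy()
    corr = np.corrcoef(sub)
    iu = np.triu_indices(len(module.members), k=1)
    return float(corr[iu].min())


def dnm_recovery_study(
    n_seeds: int = 20,
    seed: int = 0,
    module_ps: tuple[float, ...] = (0.001, 0.01, 0.05),
    alpha: float = 5.0,
) -> dict[str, float]:
    """Planted-module recovery by the DNM analysis over seeded fixtures.

    Each run generates the default three-group fixture (module of 3 sets,
    score correlation 0.8, 2x SD inflation, planted in "LSC-"), scores with
    FAIME.alpha, z-normalizes, and runs the DNM analysis at each module-p
    threshold.  Reports the exact-recovery and critical-group rates at the
    default threshold 0.01, the minimum pairwise-PCC margin over r_crit
    (complete-linkage guarantee; positive means every intra-module pair is
    individually significant), and the minimum Jaccard similarity between
    the winning modules across thresholds.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds)
    recovered = np.zeros(n_seeds, dtype=bool)
    critical_ok = np.zeros(n_seeds, dtype=bool)
    guarantee_margin = np.inf
    min_jaccard = 1.0
    for i, s in enumerate(base):
        spec = FixtureSpec(seed=int(s) % (2**31))
        expr, collection = generate_multigroup_dataset(spec)
        profile = z_normalize(score_dataset(expr, collection, ScoringConfig(alpha=alpha)))
        winners = {}
        for mp in module_ps:
            config = DNMConfig(control_group="HSC+", module_p=mp)
            result = identify_critical_group(profile, config)
            for mods in result.modules.values():
                for mod in mods:
                    m = int((profile.group == mod.group).sum())
                    from .dnm import critical_correlation

                    margin = _module_min_pcc(profile, mod) - critical_correlation(m, mp)
                    guarantee_margin = min(guarantee_margin, margin)
            if result.found:
                winners[mp] = set(result.winning_module.members)
            if mp == 0.01:
                recovered[i] = (
                    result.found
                    and set(result.winning_module.members) == set(spec.module_sets)
                )
                critical_ok[i] = result.found and result.critical_group == spec.module_group
        mps = [mp for mp in module_ps if mp in winners]
        for a in range(len(mps)):
            for b in range(a + 1, len(mps)):
                wa, wb = winners[mps[a]], winners[mps[b]]
                min_jaccard = min(min_jaccard, len(wa & wb) / len(wa | wb))
    return {
        "dnm_recovery_rate": float(recovered.mean()),
        "dnm_critical_group_rate": float(critical_ok.mean()),
        "dnm_pair_guarantee_margin": float(guarantee_margin),
        "dnm_threshold_min_jaccard": float(min_jaccard),
    }


def _survival_fixture(seed: int, planted: bool) -> tuple:
    """One single-group cohort of 200 patients with 3 S and 4 C sets."""
    spec = FixtureSpec(
        seed=seed,
        groups={"AML": 200},
        module_group=None,
        n_sets=40,
        n_genes=1500,
        censoring_fraction=0.3,
    )
    expr, collection = generate_multigroup_dataset(spec)
    profile = z_normalize(score_dataset(expr, collection, ScoringConfig()))
    s_sets = ["SET001", "SET002", "SET003"]
    c_sets = ["SET004", "SET005", "SET006", "SET007"]
    cohort = generate_survival_cohort(
        spec,
        profile,
        stratum_sets=(s_sets, c_sets) if planted else None,
        stratum_hazard_ratio=2.0 if planted else None,
    )
    return cohort, profile, s_sets, c_sets


def rxa_power_study(n_seeds: int = 50, seed: int = 0) -> dict[str, float]:
    """Stratified log-rank power with a planted stratum hazard ratio of 2.

    Cohorts of 200 patients (~70% events); the indicator is trained and
    tested on the same cohort, as in the training-cohort arm of the design.
    Reports the fraction of seeds with log-rank p < 0.01.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds)
    hits = 0
    for s in base:
        cohort, _, s_sets, c_sets = _survival_fixture(int(s) % (2**31), planted=True)
        s_coefs, c_coefs = train_indicator_weights(cohort, s_sets, c_sets)
        result = compute_indicator(cohort, s_coefs, c_coefs)
        result = stratify_and_test(result, cohort, km_tables=False)
        hits += result.logrank_p is not None and result.logrank_p < 0.01
    return {"rxa_power_rate": hits / n_seeds}


def rxa_null_calibration(n_runs: int = 100, X: int = 100, seed: int = 0) -> dict[str, float]:
    """Distribution of the empirical p-value on cohorts with no association.

    Each run draws a null cohort (survival independent of all scores),
    computes the observed stratification p for a fixed (S, C) pair, and its
    empirical p from X random disjoint draws.  Under the null the empirical
    p should be approximately uniform; reports the Kolmogorov-Smirnov
    p-value of that comparison and the mean empirical p.
    """
    base = np.random.SeedSequence(seed).generate_state(n_runs)
    emp = np.empty(n_runs)
    for i, s in enumerate(base):
        run_seed = int(s) % (2**31)
        cohort, profile, s_sets, c_sets = _survival_fixture(run_seed, planted=False)
        s_coefs, c_coefs = train_indicator_weights(cohort, s_sets, c_sets)
        result = compute_indicator(cohort, s_coefs, c_coefs)
        result = stratify_and_test(result, cohort, km_tables=False)
        observed = result.logrank_p if result.logrank_p is not None else 1.0
        emp[i], _ = empirical_pvalue(
            cohort,
            observed,
            (len(s_sets), len(c_sets)),
            list(profile.sets),
            X=X,
            seed=run_seed,
            exclude=(tuple(s_sets), tuple(c_sets)),
        )
    ks = stats.kstest(emp, "uniform")
    return {
        "rxa_null_ks_p": float(ks.pvalue),
        "rxa_null_mean_empirical_p": float(emp.mean()),
    }
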