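"""Power and type-I-error evaluation of per-sample gene-set scorers.

Expression is generated under a linear additive model

    y_ab = alpha_a + beta_ab + e_ab

for gene a and sample b, with a per-gene baseline alpha_a ~ N(0, 1), cell
noise e_ab ~ N(0, 1), and a group-dependent effect beta drawn independently
per cell: N(0, 1) for background and non-DE-set genes in both groups, and,
for the differentially expressed fraction phi of the planted DE set,
N(m, sigma_de) in group 1 versus N(0, sigma_de) in group 2.  Two disjoint
gene-sets of equal size x are planted: one carrying the shift (DE) and one
null (non-DE).

Each replicate scores both sets with the scorer under test and compares the
two groups' score vectors with a two-sample t-test.  Statistical power is the
fraction of replicates in which the DE set remains significant after
Benjamini-Hochberg adjustment across replicates at the configured FDR level;
the empirical type-I error is the fraction of replicates with unadjusted
p < 0.05 for the non-DE set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError
from .faime import GeneSetProfile

logger = logging.getLogger(__name__)

DE_SET = "DE_set"
NONDE_SET = "nonDE_set"


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulation scenario.

    Defaults follow the study design this harness reproduces: p = 5000 genes,
    planted sets of x = 30 genes, DE fractions {0.5, 0.8}, effects {0.5, 1},
    per-group sample sizes from {10, 20, 40, 60, 80, 100}, 1000 replicates,
    FDR level 0.05.
    """

    p: int = 5000
    n_per_group: int = 20
    set_size: int = 30
    de_fraction: float = 0.8
    effect: float = 0.5
    sigma_de: float = 0.5
    reps: int = 1000
    fdr_level: float = 0.05
    seed: int = 0
    equal_var: bool = True
    bh_across_reps: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.de_fraction <= 1):
            raise ValidationError("de_fraction must be in (0, 1]")
        if self.effect < 0:
            raise ValidationError("effect must be non-negative")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if 2 * self.set_size > self.p:
            raise ValidationError("two disjoint planted sets exceed the gene count")


@dataclass
class SimulationResult:
    """Power and type-I error with per-replicate p-values retained."""

    power: float
    type1: float
    de_pvalues: np.ndarray
    nonde_pvalues: np.ndarray
    config: SimulationConfig
    scorer_name: str


def simulate_expression(
    config: SimulationConfig, rep_seed: int | np.random.SeedSequence
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Draw one replicate of the additive model with planted DE/non-DE sets.

    Genes 0..x-1 form the DE set (its first round(phi*x) genes carry the
    shift) and genes x..2x-1 the non-DE set; the remainder is background.
    Group labels are "g1" (shifted) and "g2".
    """
    rng = np.random.default_rng(rep_seed)
    p, n, x = config.p, config.n_per_group, config.set_size
    n_de = int(round(config.de_fraction * x))
    if not np.isclose(config.de_fraction * x, n_de):
        logger.info("de_fraction*set_size=%.2f not integral; rounded to %d", config.de_fraction * x, n_de)

    gene_effect = rng.standard_normal((p, 1))  # alpha_a, shared by both groups
    noise = rng.standard_normal((p, 2 * n))
    beta = rng.standard_normal((p, 2 * n))  # N(0,1) group effect for null genes
    # shifted fraction of the DE set: N(m, sigma_de) in group 1, N(0, sigma_de) in group 2
    beta[:n_de, :n] = config.effect + config.sigma_de * rng.standard_normal((n_de, n))
    beta[:n_de, n:] = config.sigma_de * rng.standard_normal((n_de, n))
    y = gene_effect + beta + noise

    genes = pd.Index([f"G{i:05d}" for i in range(p)], name="gene")
    samples = pd.Index([f"S{i:03d}" for i in range(2 * n)], name="sample")
    group = pd.Series(["g1"] * n + ["g2"] * n, index=samples, name="group")
    expr = ExpressionMatrix(pd.DataFrame(y, index=genes, columns=samples), group=group)
    collection = GeneSetCollection(
        {
            DE_SET: GeneSet(DE_SET, "planted differentially expressed set", tuple(genes[:x])),
            NONDE_SET: GeneSet(NONDE_SET, "planted null set", tuple(genes[x : 2 * x])),
        },
        min_size=min(5, x),
    )
    return expr, collection


def _set_pvalue(profile: GeneSetProfile, set_name: str, equal_var: bool) -> float:
    scores = profile.scores.loc[set_name]
    g = profile.group
    a = scores[g == "g1"].to_numpy(dtype=float)
    b = scores[g == "g2"].to_numpy(dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("degenerate score variance for %s; p set to 1", set_name)
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def evaluate_scorer(config: SimulationConfig, scorer) -> SimulationResult:
    """Run the replicate loop for one scorer and summarize power and type-I error.

    *scorer* maps (ExpressionMatrix, GeneSetCollection) -> GeneSetProfile.
    A master seed spawns independent per-replicate child seeds, so results
    are bitwise reproducible for a fixed config.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    de_p = np.empty(config.reps)
    nonde_p = np.empty(config.reps)
    for r, child in enumerate(children):
        expr, collection = simulate_expression(config, child)
        profile = scorer(expr, collection)
        de_p[r] = _set_pvalue(profile, DE_SET, config.equal_var)
        nonde_p[r] = _set_pvalue(profile, NONDE_SET, config.equal_var)
    if config.bh_across_reps:
        adjusted = stats.false_discovery_control(de_p, method="bh")
        power = float(np.mean(adjusted < config.fdr_level))
    else:
        # non-default per-replicate reading: each replicate adjusts its own
        # two p-values (DE and non-DE) jointly
        power = float(
            np.mean(
                [
                    stats.false_discovery_control([dp, np_], method="bh")[0] < config.fdr_level
                    for dp, np_ in zip(de_p, nonde_p)
                ]
            )
        )
    type1 = float(np.mean(nonde_p < 0.05))
    name = getattr(scorer, "__name__", scorer.__class__.__name__)
    return SimulationResult(power, type1, de_p, nonde_p, config, name)
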