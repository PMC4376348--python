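"""Dynamic Network Mechanism (DNM) analysis on gene-set profiles.

DNM lifts dynamical-network-biomarker analysis from genes to gene-sets.  The
premise: approaching a critical transition, a small module of gene-sets shows
simultaneously (i) high score variability within the transitional sample
group, (ii) strong mutual correlation within the module, and (iii) weak
correlation with gene-sets outside it.  For each sample group t the analysis

  1. keeps the top fraction (default 5%) of gene-sets by score SD within t;
  2. clusters the candidates by complete-linkage hierarchical clustering on
     the distance 1 - PCC of their score vectors in t, cutting the dendrogram
     at 1 - r_crit where r_crit is the minimal correlation significant at the
     configured two-sided level (df = m - 2); complete linkage then
     guarantees every intra-module pair has PCC >= r_crit;
  3. picks control gene-sets: the n sets outside the module with the highest
     max |PCC| to any member, computed in the designated control group;
  4. scores each module S_tI = SD_tI * PCC_I / PCC_O, where SD_tI is the mean
     member score SD in t, PCC_I the mean absolute member-pair correlation in
     t, and PCC_O the mean absolute member-control correlation in t.

The module with the globally largest S identifies the critical sample group.
A three-way hypergeometric overlap test quantifies gene sharing among the
winning module's member sets against a background of N genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datasets import GeneSetCollection, ValidationError
from .normalize import NormalizedProfile

logger = logging.getLogger(__name__)

PCC_O_FLOOR = 1e-6


@dataclass(frozen=True)
class DNMConfig:
    """DNM tuning parameters.

    sd_quantile : fraction of gene-sets kept as high-variance candidates
        (default 0.05, i.e. top 5% by SD; the cut is a ceiling).
    module_p : two-sided significance level defining the minimal intra-module
        correlation (default 0.01; 0.001 and 0.05 give comparable modules).
    n_controls : controls per module — 5 suits small/middle collections
        (pathways, motifs), 20 the large ones (CGP scale).
    control_group : label of the reference (normal) group used for control
        selection.
    """

    control_group: str = ""
    sd_quantile: float = 0.05
    module_p: float = 0.01
    n_controls: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.sd_quantile <= 1):
            raise ValidationError("sd_quantile must be in (0, 1]")
        if not (0 < self.module_p < 1):
            raise ValidationError("module_p must be in (0, 1)")
        if self.n_controls < 1:
            raise ValidationError("n_controls must be >= 1")


@dataclass
class DNMModule:
    """One candidate module with its controls and combined score."""

    group: str
    members: tuple[str, ...]
    controls: tuple[str, ...]
    sd_mean: float
    pcc_in: float
    pcc_out: float
    score: float
    pcc_out_floored: bool = False


@dataclass
class DNMResult:
    """Per-group candidate modules and the globally winning one."""

    modules: dict[str, list[DNMModule]]
    critical_group: str | None
    winning_module: DNMModule | None
    r_crit: dict[str, float]
    found: bool
    tied: bool = False


def critical_correlation(m: int, module_p: float) -> float:
    """Minimal |r| whose two-sided correlation t-test p equals module_p (df = m-2)."""
    if m < 4:
        raise ValidationError("correlation significance needs >= 4 samples")
    df = m - 2
    t_crit = stats.t.ppf(1 - module_p / 2, df)
    return float(t_crit / math.sqrt(df + t_crit**2))


def _group_values(profile: NormalizedProfile, group: str) -> pd.DataFrame:
    if profile.group is None:
        raise ValidationError("profile has no group annotation")
    cols = profile.samples[(profile.group == group).to_numpy()]
    return profile.values[cols]


def select_high_variance_sets(
    profile: NormalizedProfile, group: str, sd_quantile: float = 0.05
) -> list[str]:
    """Names of the top ceil(sd_quantile * n_sets) sets by SD within *group*.

    Returned in descending SD order with a stable tie-break by set name.
    """
    sub = _group_values(profile, group)
    if sub.shape[1] < 3:
        raise ValidationError(f"group {group!r} has fewer than 3 samples")
    sds = sub.std(axis=1, ddof=1)
    k = math.ceil(sd_quantile * len(sds))
    order = sorted(sds.index, key=lambda name: (-sds[name], name))
    return order[:k]


def cluster_modules(
    profile: NormalizedProfile,
    group: str,
    candidates: list[str],
    module_p: float = 0.01,
) -> list[tuple[str, ...]]:
    """Complete-linkage clustering of candidate score vectors at distance 1 - PCC.

    The dendrogram is cut at height 1 - r_crit so that every pair within a
    returned module is significantly correlated at *module_p*.  Singleton
    clusters are discarded.  Members of each module are sorted by name;
    modules are ordered by first member.
    """
    if len(candidates) < 2:
        return []
    sub = _group_values(profile, group)
    m = sub.shape[1]
    r_crit = critical_correlation(m, module_p)
    x = sub.loc[candidates].to_numpy(dtype=float)
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize roundoff
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - r_crit, criterion="distance")
    modules: list[tuple[str, ...]] = []
    for lab in np.unique(labels):
        members = tuple(sorted(str(c) for c in np.asarray(candidates)[labels == lab]))
        if len(members) >= 2:
            modules.append(members)
    modules.sort()
    return modules


def select_control_sets(
    profile: NormalizedProfile,
    members: tuple[str, ...],
    control_group: str,
    n_controls: int = 5,
) -> tuple[str, ...]:
    """Top-correlated non-member sets in the control group.

    Each pool set is ranked by its maximum |PCC| with any module member,
    computed over the control group's samples; ties break by name.  If the
    pool is smaller than n_controls the whole pool is returned with a warning.
    """
    sub = _group_values(profile, control_group)
    pool = [s for s in profile.sets if s not in set(members)]
    if not pool:
        raise ValidationError("no gene-sets outside the module to draw controls from")
    mem = sub.loc[list(members)].to_numpy(dtype=float)
    rest = sub.loc[pool].to_numpy(dtype=float)
    corr = _cross_corr(rest, mem)
    stat = np.nanmax(np.abs(corr), axis=1)
    stat = np.where(np.isnan(stat), -np.inf, stat)  # constant pool vectors rank last
    order = sorted(range(len(pool)), key=lambda i: (-stat[i], pool[i]))
    if len(pool) < n_controls:
        logger.warning(
            "control pool (%d) smaller than n_controls (%d); returning entire pool",
            len(pool), n_controls,
        )
        return tuple(pool[i] for i in order)
    return tuple(pool[i] for i in order[:n_controls])


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of a and rows of b (len(a) x len(b))."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a @ b.T) / np.outer(sa, sb)


def score_module(
    profile: NormalizedProfile,
    members: tuple[str, ...],
    controls: tuple[str, ...],
    group: str,
) -> DNMModule:
    """Combined score S = SD_tI * PCC_I / PCC_O for one module in group t.

    Absolute correlations are used throughout; PCC_O is floored at 1e-6 (and
    the module flagged) to keep the ratio finite.
    """
    if len(members) < 2:
        raise ValidationError("module needs >= 2 members")
    if not controls:
        raise ValidationError("module needs >= 1 control")
    sub = _group_values(profile, group)
    mem = sub.loc[list(members)].to_numpy(dtype=float)
    ctl = sub.loc[list(controls)].to_numpy(dtype=float)
    sd_mean = float(np.mean(np.std(mem, axis=1, ddof=1)))
    cin = _cross_corr(mem, mem)
    iu = np.triu_indices(len(members), k=1)
    pcc_in = float(np.mean(np.abs(cin[iu])))
    pcc_out = float(np.mean(np.abs(_cross_corr(mem, ctl))))
    floored = pcc_out < PCC_O_FLOOR
    if floored:
        logger.warning("PCC_O=%.2e below floor for module %s; floored", pcc_out, members)
        pcc_out = PCC_O_FLOOR
    return DNMModule(
        group=group,
        members=members,
        controls=controls,
        sd_mean=sd_mean,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        score=sd_mean * pcc_in / pcc_out,
        pcc_out_floored=floored,
    )


def identify_critical_group(profile: NormalizedProfile, config: DNMConfig) -> DNMResult:
    """Run the full per-group DNM pipeline and pick the max-scoring module.

    All groups (including the control group) are analyzed.  Ties on the
    combined score go to the lexicographically lowest group label and are
    flagged.
    """
    if profile.group is None:
        raise ValidationError("profile has no group annotation")
    groups = sorted(profile.group.unique())
    if len(groups) < 2:
        raise ValidationError("DNM needs at least 2 sample groups")
    if config.control_group not in groups:
        raise ValidationError(f"control group {config.control_group!r} not among {groups}")
    per_group: dict[str, list[DNMModule]] = {}
    r_crit: dict[str, float] = {}
    for g in groups:
        m = int((profile.group == g).sum())
        r_crit[g] = critical_correlation(m, config.module_p)
        candidates = select_high_variance_sets(profile, g, config.sd_quantile)
        scored = []
        for members in cluster_modules(profile, g, candidates, config.module_p):
            controls = select_control_sets(profile, members, config.control_group, config.n_controls)
            scored.append(score_module(profile, members, controls, g))
        per_group[g] = scored
    all_modules = [mod for mods in per_group.values() for mod in mods]
    if not all_modules:
        logger.warning("no multi-member module in any group: no DNM found")
        return DNMResult(per_group, None, None, r_crit, found=False)
    best_score = max(mod.score for mod in all_modules)
    winners = [mod for mod in all_modules if mod.score == best_score]
    winners.sort(key=lambda mod: mod.group)
    tied = len(winners) > 1
    if tied:
        logger.warning("combined-score tie across groups %s; lowest label wins",
                       [w.group for w in winners])
    win = winners[0]
    return DNMResult(per_group, win.group, win, r_crit, found=True, tied=tied)


def overlap_pvalue(A: int, B: int, C: int, N: int, n_shared: int) -> float:
    """Three-set hypergeometric overlap probability.

    Decomposes the event "n genes are shared" over k, the overlap of the
    first two sets: the probability that sets of sizes A and B drawn from N
    background genes share exactly k genes, times the hypergeometric
    probability that the third set of size C hits exactly n - k of the
    A + B - 2k genes belonging to exactly one of the first two:

        sum_{k=0}^{n} [C(A,k) C(N-A,B-k) / C(N,B)]
                    * [C(A+B-2k, n-k) C(N-A-B+2k, C-n+k) / C(N,C)]

    evaluated with exact integer binomials (terms with impossible binomial
    arguments contribute zero).  Both fractions are proper hypergeometric
    mass functions, so the value lies in [0, 1] and the degenerate case
    A = B = C = n = N returns exactly 1.
    """
    for name, v in (("A", A), ("B", B), ("C", C)):
        if not (0 <= v <= N):
            raise ValidationError(f"{name} must satisfy 0 <= {name} <= N")
    if n_shared < 0:
        raise ValidationError("n_shared must be non-negative")

    def comb(a: int, b: int) -> int:
        if a < 0 or b < 0 or b > a:
            return 0
        return math.comb(a, b)

    denom = Fraction(comb(N, B)) * comb(N, C)
    if denom == 0:
        raise ValidationError("invalid background size")
    total = Fraction(0)
    for k in range(n_shared + 1):
        t1 = comb(A, k) * comb(N - A, B - k)
        t2 = comb(A + B - 2 * k, n_shared - k) * comb(N - A - B + 2 * k, C - n_shared + k)
        total += Fraction(t1) * t2
    return float(total / denom)
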