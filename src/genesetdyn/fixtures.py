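"""Synthetic multi-group, multi-dataset expression and survival generators.

These generators emulate the structure the analysis pipeline is built for —
several sorted sample groups profiled across heterogeneous datasets, with a
small module of gene-sets that co-fluctuates with inflated variance in
exactly one group, and survival outcomes driven by designated gene-set
scores — without attempting to mimic real AML expression marginals or
platform-specific noise.

Planted-module construction: for samples of the target group, each gene of a
member set s takes

    inflation * (sqrt(rho) * F_k + sqrt(1 - rho) * G_{s,k}) + tau * eps

where F_k is a per-sample latent factor shared by the whole module, G_{s,k}
a per-set factor, and eps independent gene-level noise.  The shared/specific
split gives set-level score correlation rho in expectation, and the
inflation factor raises within-group score SD; in all other groups the same
genes are plain N(0, 1) background.  Dataset heterogeneity is simulated by
per-(gene, dataset) additive offsets plus a per-dataset scale, the kind of
platform effect the inter-dataset z-normalization is meant to absorb.

Survival times are exponential with log-hazard linear in designated gene-set
scores (the simplest proportional-hazards model, matching the Cox machinery
being tested); censoring is by an independent exponential time whose rate is
matched to the requested censoring fraction at the baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError
from .normalize import NormalizedProfile
from .rxa import SurvivalCohort

DEFAULT_GROUPS = {"HSC+": 23, "LSC+": 77, "LSC-": 59}


@dataclass
class FixtureSpec:
    """Shape and planted structure of a synthetic study.

    Defaults give three sorted groups with the study-scale sample counts
    (23 / 77 / 59), two platforms, 80 disjoint gene-sets of 10-30 genes over
    2000 genes, and a 3-set module planted in "LSC-" with score correlation
    0.8 and 2x SD inflation.
    """

    n_genes: int = 2000
    n_sets: int = 80
    set_size: tuple[int, int] = (10, 30)
    groups: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_datasets: int = 2
    dataset_shift_sd: float = 0.3
    dataset_scale_range: tuple[float, float] = (0.8, 1.25)
    module_sets: tuple[str, ...] = ("SET001", "SET002", "SET003")
    module_group: str | None = "LSC-"
    module_rho: float = 0.8
    module_sd_inflation: float = 2.0
    module_noise_sd: float = 0.5
    baseline_hazard: float = 0.1
    loghazard: Mapping[str, float] = field(default_factory=dict)
    censoring_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.module_rho < 1):
            raise ValidationError("module correlation rho must be in [0, 1)")
        if not (0 <= self.censoring_fraction < 1):
            raise ValidationError("censoring fraction must be in [0, 1)")
        if not np.isfinite(self.baseline_hazard) or self.baseline_hazard <= 0:
            raise ValidationError("baseline hazard must be positive and finite")


def _set_name(i: int) -> str:
    return f"SET{i + 1:03d}"


def generate_multigroup_dataset(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Draw one synthetic expression matrix and its gene-set collection.

    Gene-sets occupy disjoint consecutive gene blocks; background expression
    is N(0, 1).  Deterministic for a fixed spec (seeded by ``spec.seed``
    unless an explicit generator is passed).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.set_size
    sizes = rng.integers(lo, hi + 1, size=spec.n_sets)
    if sizes.sum() > spec.n_genes:
        raise ValidationError(
            f"gene-set sizes ({sizes.sum()}) exceed n_genes ({spec.n_genes})"
        )
    genes = pd.Index([f"G{i:05d}" for i in range(spec.n_genes)], name="gene")
    sets: dict[str, GeneSet] = {}
    blocks: dict[str, np.ndarray] = {}
    start = 0
    for i, size in enumerate(sizes):
        name = _set_name(i)
        idx = np.arange(start, start + size)
        blocks[name] = idx
        sets[name] = GeneSet(name, f"synthetic block set {i + 1}", tuple(genes[idx]))
        start += size
    collection = GeneSetCollection(sets)
    for ms in spec.module_sets:
        if ms not in collection:
            raise ValidationError(f"planted module set {ms!r} not in the collection")

    samples, group_labels = [], []
    for g, count in spec.groups.items():
        for k in range(count):
            samples.append(f"{g}_{k:03d}")
            group_labels.append(g)
    samples = pd.Index(samples, name="sample")
    group = pd.Series(group_labels, index=samples, name="group")
    n_samples = len(samples)

    values = rng.standard_normal((spec.n_genes, n_samples))

    if spec.module_group is not None:
        if spec.module_group not in spec.groups:
            raise ValidationError(f"module group {spec.module_group!r} not among groups")
        target = np.flatnonzero((group == spec.module_group).to_numpy())
        shared = rng.standard_normal(len(target))  # per-sample latent factor F_k
        for name in spec.module_sets:
            specific = rng.standard_normal(len(target))  # per-set factor G_{s,k}
            latent = np.sqrt(spec.module_rho) * shared + np.sqrt(1 - spec.module_rho) * specific
            gidx = blocks[name]
            noise = rng.standard_normal((len(gidx), len(target)))
            values[np.ix_(gidx, target)] = (
                spec.module_sd_inflation * latent[None, :] + spec.module_noise_sd * noise
            )

    dataset = pd.Series(
        [f"D{(i % spec.n_datasets) + 1}" for i in range(n_samples)], index=samples, name="dataset"
    )
    scales = rng.uniform(*spec.dataset_scale_range, size=spec.n_datasets)
    offsets = spec.dataset_shift_sd * rng.standard_normal((spec.n_genes, spec.n_datasets))
    for d in range(spec.n_datasets):
        cols = np.flatnonzero((dataset == f"D{d + 1}").to_numpy())
        values[:, cols] = scales[d] * values[:, cols] + offsets[:, [d]]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), group=group, dataset=dataset
    )
    return expr, collection


def generate_survival_cohort(
    spec: FixtureSpec,
    profile: NormalizedProfile,
    rng: np.random.Generator | None = None,
    stratum_sets: tuple[list[str], list[str]] | None = None,
    stratum_hazard_ratio: float | None = None,
) -> SurvivalCohort:
    """Draw exponential survival outcomes for the profile's samples.

    By default the per-sample log-hazard is linear in the gene-set scores
    named by ``spec.loghazard``.  Alternatively, ``stratum_sets=(S, C)`` with
    ``stratum_hazard_ratio`` plants a fixed hazard ratio between the two
    strata defined by the sign of (mean C score - mean S score), the
    structure the gene-set-pair indicator is designed to recover.
    Censoring is independent exponential at rate matched to the requested
    fraction under the baseline hazard.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    vals = profile.values
    n = vals.shape[1]
    log_hr = np.zeros(n)
    if stratum_sets is not None:
        if stratum_hazard_ratio is None or stratum_hazard_ratio <= 0:
            raise ValidationError("stratum_hazard_ratio must be positive")
        s_names, c_names = stratum_sets
        poor = (
            vals.loc[list(c_names)].mean(axis=0) - vals.loc[list(s_names)].mean(axis=0)
        ).to_numpy() > 0
        log_hr = np.where(poor, np.log(stratum_hazard_ratio), 0.0)
    elif spec.loghazard:
        for name, beta in spec.loghazard.items():
            if name not in vals.index:
                raise ValidationError(f"loghazard refers to unknown gene-set {name!r}")
            log_hr = log_hr + beta * vals.loc[name].to_numpy(dtype=float)
    hazard = spec.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    c = spec.censoring_fraction
    if c > 0:
        censor_rate = spec.baseline_hazard * c / (1 - c)
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return SurvivalCohort(
        pd.Series(time, index=vals.columns, name="time"),
        pd.Series(event, index=vals.columns, name="event"),
        vals,
    )


def write_fixture_files(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    outdir,
    cohort: SurvivalCohort | None = None,
) -> None:
    """Write expr.tsv, sets.gmt, annot.tsv (and surv.tsv) to *outdir*."""
    from pathlib import Path

    from .datasets import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(outdir / "expr.tsv")
    write_gmt(collection, outdir / "sets.gmt")
    ann = pd.DataFrame({"sample": expr.samples})
    if expr.group is not None:
        ann["group"] = expr.group.to_numpy()
    if expr.dataset is not None:
        ann["dataset"] = expr.dataset.to_numpy()
    ann.to_csv(outdir / "annot.tsv", sep="\t", index=False)
    if cohort is not None:
        pd.DataFrame(
            {"sample": cohort.samples, "time": cohort.time.to_numpy(), "event": cohort.event.to_numpy()}
        ).to_csv(outdir / "surv.tsv", sep="\t", index=False)
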