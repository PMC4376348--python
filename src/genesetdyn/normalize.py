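"""Inter-dataset normalization of gene-set profiles.

Gene-set scores from different platforms or cohorts live on different scales.
The z-transform applied here standardizes each sample column over its N
gene-set scores — subtract the column mean, divide by the population standard
deviation (divisor N) — making profiles from disparate datasets directly
comparable, symmetric and zero-centered.

Because the transform acts on each sample column independently, normalizing
per dataset and then merging is identical to merging and then normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ValidationError
from .faime import GeneSetProfile


class DomainError(ValueError):
    pass


@dataclass
class NormalizedProfile:
    """Per-sample z-scored gene-set x sample matrix with provenance."""

    values: pd.DataFrame
    group: pd.Series | None = None
    dataset: pd.Series | None = None

    @property
    def sets(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def z_normalize(profile: GeneSetProfile | NormalizedProfile) -> NormalizedProfile:
    """Center and scale each sample column over its gene-set scores.

    Uses the population standard deviation (divisor N).  Idempotent, and
    invariant to per-column affine maps a*x + b with a > 0.
    """
    mat = profile.values if isinstance(profile, NormalizedProfile) else profile.scores
    if mat.shape[0] < 2:
        raise ValidationError("normalization requires at least 2 gene-sets per sample")
    x = mat.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        raise DomainError(f"constant score column(s), sample(s): {list(mat.columns[bad])}")
    z = (x - mu) / sigma
    return NormalizedProfile(
        pd.DataFrame(z, index=mat.index, columns=mat.columns),
        group=profile.group,
        dataset=profile.dataset,
    )


def merge_profiles(profiles: Sequence[NormalizedProfile]) -> NormalizedProfile:
    """Column-concatenate normalized profiles sharing one gene-set universe.

    Profiles with differing gene-set row indices are refused: silently
    intersecting would change N and break cross-dataset comparability.
    Row order of the result is canonicalized by sorting set names.
    """
    if not profiles:
        raise ValidationError("no profiles to merge")
    universe = set(profiles[0].sets)
    for p in profiles[1:]:
        other = set(p.sets)
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ValidationError(f"gene-set indices differ between profiles: {diff[:10]}")
    order = sorted(universe)
    values = pd.concat([p.values.loc[order] for p in profiles], axis=1)

    def _concat_ann(attr: str) -> pd.Series | None:
        anns = [getattr(p, attr) for p in profiles]
        if any(a is None for a in anns):
            return None
        return pd.concat(anns)

    return NormalizedProfile(values, group=_concat_ann("group"), dataset=_concat_ann("dataset"))
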