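"""Gene-set collections and expression matrices.

Provides the two input containers everything downstream consumes: a
:class:`GeneSetCollection` parsed from GMT (MSigDB dialect) and an
:class:`ExpressionMatrix` (gene x sample, with optional per-sample group and
dataset labels).  Also implements the two preprocessing steps required before
scoring: collapsing probe-level measurements to one row per gene (keeping, for
each gene, the probe with the highest mean expression) and restricting
gene-sets to the measured gene universe with a minimum-size filter.

Gene symbols are matched exactly and case-sensitively; no alias resolution is
attempted.  Genes of a set that are not measured are dropped (and logged),
never imputed as zero expression.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5  # smallest usable gene-set after restriction to measured genes


class GmtParseError(ValueError):
    """A GMT line could not be parsed."""


class ValidationError(ValueError):
    """An input container violates a structural invariant."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene-set name must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene-set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, universe: set[str]) -> "GeneSet":
        """Intersect with *universe*, preserving original gene order."""
        kept = tuple(g for g in self.genes if g in universe)
        return GeneSet(self.name, self.description, kept)


@dataclass
class GeneSetCollection:
    """A mapping of set name -> :class:`GeneSet` with a size filter."""

    sets: dict[str, GeneSet]
    min_size: int = DEFAULT_MIN_SIZE

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValidationError("min_size must be a positive integer")
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"key {name!r} does not match set name {gs.name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def membership_matrix(self, genes: pd.Index) -> pd.DataFrame:
        """Boolean set x gene indicator matrix over *genes*."""
        gene_pos = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((len(self.sets), len(genes)), dtype=bool)
        for row, gs in enumerate(self):
            for g in gs.genes:
                pos = gene_pos.get(g)
                if pos is not None:
                    mat[row, pos] = True
        return pd.DataFrame(mat, index=pd.Index(self.names, name="gene_set"), columns=genes)


def read_gmt(path: str | Path, min_size: int = DEFAULT_MIN_SIZE) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Duplicate gene symbols within a line are de-duplicated preserving first
    occurrence; duplicate set names across lines are rejected.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]  # tolerate trailing empty fields
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.debug("GMT line %d (%s): removed duplicate gene symbols", lineno, name)
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = GeneSet(name, description, deduped)
    return GeneSetCollection(sets, min_size=min_size)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


@dataclass
class ExpressionMatrix:
    """Gene x sample real matrix with optional per-sample annotations.

    Values may be log2 microarray intensities or RNA-seq counts; downstream
    scoring is rank-based and therefore invariant to any strictly monotone
    per-sample transform of the values.
    """

    values: pd.DataFrame
    group: pd.Series | None = None
    dataset: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        for attr in ("group", "dataset"):
            ann = getattr(self, attr)
            if ann is not None:
                missing = v.columns.difference(ann.index)
                if len(missing):
                    raise ValidationError(f"{attr} annotation missing for samples: {list(missing)[:5]}")
                setattr(self, attr, ann.reindex(v.columns))

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[samples],
            None if self.group is None else self.group[samples],
            None if self.dataset is None else self.dataset[samples],
        )

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        annotations: pd.DataFrame | None = None,
        sep: str = "\t",
    ) -> "ExpressionMatrix":
        """Read a delimited matrix: first column gene symbol, header of samples."""
        values = pd.read_csv(path, sep=sep, index_col=0)
        group = dataset = None
        if annotations is not None:
            if "group" in annotations:
                group = annotations["group"]
            if "dataset" in annotations:
                dataset = annotations["dataset"]
        return cls(values, group, dataset)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample, group[, dataset]."""
    ann = pd.read_csv(path, sep="\t")
    if "sample" not in ann.columns:
        raise ValidationError("annotation table must contain a 'sample' column")
    if ann["sample"].duplicated().any():
        raise ValidationError("annotation table has duplicate sample identifiers")
    return ann.set_index("sample")


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    group: pd.Series | None = None,
    dataset: pd.Series | None = None,
) -> ExpressionMatrix:
    """Collapse a probe x sample matrix to one row per gene.

    For each gene with multiple probes, the single probe with the highest mean
    expression across samples is kept (ties broken by input file order).
    Probes absent from *probe_to_gene* are dropped.
    """
    if not probe_to_gene:
        raise ValidationError("probe_to_gene mapping is empty")
    mapped = probe_values.index[probe_values.index.isin(probe_to_gene)]
    if not len(mapped):
        raise ValidationError("no probe maps to a gene symbol")
    dropped = probe_values.shape[0] - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = probe_values.loc[mapped]
    info = pd.DataFrame(
        {
            "gene": [probe_to_gene[p] for p in sub.index],
            "mean": sub.mean(axis=1).to_numpy(),
            "order": np.arange(len(sub)),
        },
        index=sub.index,
    )
    # stable sort: highest mean first, original order breaks ties
    info = info.sort_values(["gene", "mean", "order"], ascending=[True, False, True], kind="stable")
    winners = info.drop_duplicates("gene", keep="first")
    collapsed = sub.loc[winners.index]
    collapsed.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, group, dataset)


def restrict_sets(collection: GeneSetCollection, expr: ExpressionMatrix) -> GeneSetCollection:
    """Intersect every set with the measured genes; drop sets below min_size.

    Idempotent.  Raises :class:`ValidationError` if no set survives.
    """
    if not len(collection) or not expr.n_genes:
        raise ValidationError("collection and expression matrix must be non-empty")
    universe = set(expr.genes)
    kept: dict[str, GeneSet] = {}
    removed: list[str] = []
    for gs in collection:
        restricted = gs.restrict(universe)
        if len(restricted) >= collection.min_size:
            kept[restricted.name] = restricted
        else:
            removed.append(gs.name)
    if removed:
        logger.info(
            "restrict_sets: removed %d sets below min_size=%d: %s%s",
            len(removed), collection.min_size, removed[:10], "..." if len(removed) > 10 else "",
        )
    if not kept:
        raise ValidationError("all gene-sets removed by restriction to measured genes")
    return GeneSetCollection(kept, min_size=collection.min_size)
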