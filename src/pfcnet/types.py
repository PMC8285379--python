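"""Shared domain types for the protein-cluster pipeline.

The pipeline works on protein catalogs predicted from metagenome-assembled
genomes (MAGs), pairwise similarity hits between those proteins, per-gene read
counts, and an environmental table describing the samples.  The types here are
thin, validated containers; matrices are plain :class:`pandas.DataFrame`
objects (features in rows, samples in columns for abundance tables; samples in
rows for environmental tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: taxonomic ranks carried for every MAG, highest first
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: sentinel for a rank with no assignment
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: sequence, source MAG, gene length, annotations.

    ``gene_length_nt`` is the length of the underlying *nucleotide* gene (used
    by the abundance normalization), not the amino-acid length.
    """

    protein_id: str
    sequence: str
    mag_id: str
    gene_length_nt: int
    kegg_ids: frozenset[str] = frozenset()
    kegg_pathways: frozenset[str] = frozenset()
    eggnog_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )
        if self.gene_length_nt < 3:
            raise ValueError(
                f"protein {self.protein_id!r}: gene_length_nt must be >= 3"
            )

    @property
    def is_annotated(self) -> bool:
        return bool(self.kegg_ids or self.eggnog_terms)


@dataclass(frozen=True)
class MagTaxonomy:
    """Taxonomic assignment of one MAG, domain down to genus.

    A rank may be :data:`UNANNOTATED` only if every rank below it is too (an
    assignment cannot resume once it stops).
    """

    mag_id: str
    ranks: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.ranks]
        if missing:
            raise ValueError(f"MAG {self.mag_id!r}: missing ranks {missing}")
        if self.ranks["domain"] == UNANNOTATED:
            raise ValueError(f"MAG {self.mag_id!r}: domain must be annotated")
        seen_gap = False
        for r in RANKS:
            if self.ranks[r] == UNANNOTATED:
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    f"MAG {self.mag_id!r}: rank {r!r} annotated below an "
                    "unannotated rank"
                )

    def annotated_at(self, rank: str) -> bool:
        return self.ranks[rank] != UNANNOTATED

    @property
    def deepest_rank(self) -> str | None:
        """Deepest annotated rank name, or None below domain (never happens)."""
        deepest = None
        for r in RANKS:
            if self.ranks[r] != UNANNOTATED:
                deepest = r
        return deepest


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit after self-hit removal and collapsing.

    Coverages are percentages of each side's sequence spanned by the
    alignment, clamped to [0, 100].
    """

    query_id: str
    subject_id: str
    pident: float
    cov_query: float
    cov_subject: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit {self.query_id!r} not allowed")
        for name in ("pident", "cov_query", "cov_subject"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} out of [0, 100]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair key."""
        return tuple(sorted((self.query_id, self.subject_id)))  # type: ignore[return-value]


@dataclass(frozen=True)
class PfcPartition:
    """Partition of a protein catalog into clusters (size >= 2) + singletons.

    Cluster ids are consecutive integers from 1, assigned by sorting clusters
    on their lexicographically smallest member id.
    """

    clusters: Mapping[int, frozenset[str]]
    singletons: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValueError(f"cluster {cid}: fewer than 2 members")
            if seen & members:
                raise ValueError(f"cluster {cid}: overlaps another cluster")
            seen |= members
        if seen & self.singletons:
            raise ValueError("singletons overlap clusters")
        ids = sorted(self.clusters)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be consecutive from 1")

    @property
    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for members in self.clusters.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class CountTable:
    """Raw mapped-read counts per gene per sample plus normalization sidecars.

    ``totals`` are *sequenced* reads per sample (mapped + unmapped), so column
    sums of ``counts`` may exceed or undershoot them; counts may be fractional
    (probabilistic read assignment upstream).
    """

    counts: pd.DataFrame  # genes x samples
    lengths_nt: pd.Series  # per gene
    totals: pd.Series  # per sample

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.equals(self.lengths_nt.index):
            self.lengths_nt = self.lengths_nt.reindex(self.counts.index)
        if self.lengths_nt.isna().any():
            missing = self.lengths_nt.index[self.lengths_nt.isna()][0]
            raise ValueError(f"no gene length for {missing!r}")
        if not self.counts.columns.equals(self.totals.index):
            self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any():
            missing = self.totals.index[self.totals.isna()][0]
            raise ValueError(f"no total read count for sample {missing!r}")


@dataclass
class EnvironmentTable:
    """Samples x variables table with declared quantitative/qualitative types.

    Quantitative columns are floats and may contain NaN before imputation;
    qualitative columns are strings over a finite level set.
    """

    data: pd.DataFrame  # samples x variables
    quantitative: list[str] = field(default_factory=list)
    qualitative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        declared = set(self.quantitative) | set(self.qualitative)
        cols = set(self.data.columns)
        if declared != cols:
            raise ValueError(
                f"declared variables {sorted(declared)} != columns {sorted(cols)}"
            )
        if set(self.quantitative) & set(self.qualitative):
            raise ValueError("variable declared both quantitative and qualitative")
        for v in self.quantitative:
            if not np.issubdtype(self.data[v].dtype, np.number):
                raise ValueError(f"quantitative variable {v!r} is not numeric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, variables: Sequence[str]) -> "EnvironmentTable":
        variables = list(variables)
        return EnvironmentTable(
            data=self.data[variables].copy(),
            quantitative=[v for v in self.quantitative if v in variables],
            qualitative=[v for v in self.qualitative if v in variables],
        )

    def copy(self) -> "EnvironmentTable":
        return EnvironmentTable(
            data=self.data.copy(),
            quantitative=list(self.quantitative),
            qualitative=list(self.qualitative),
        )


def check_abundance_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a features x samples abundance matrix (non-negative, complete)."""
    if df.isna().any().any():
        raise ValueError("abundance matrix contains missing entries")
    if (df.values < 0).any():
        raise ValueError("abundance matrix contains negative values")
    return df
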