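"""Per-cluster functional and taxonomic scoring.

Functional homogeneity of a cluster with ``N_prot`` member proteins and
``N_annot`` unique annotation terms is ``1 - N_annot / N_prot`` (1 when a
single unique term, undefined when no member is annotated), floored at 0 so
multi-term proteins cannot push the score negative.  A cluster is "dark" when
it has no functional annotation in either database (KEGG, eggNOG) and no
member taxonomy below the phylum level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import RANKS, MagTaxonomy, PfcPartition, ProteinRecord

#: ranks entering the taxonomy profile (domain is summarized separately)
PROFILE_RANKS = RANKS[1:]  # phylum .. genus


def functional_homogeneity(annotation_terms_per_protein: Sequence[set | frozenset]) -> float | None:
    """Homogeneity score of one cluster for one annotation database.

    ``None`` (missing) when no member carries any term.  Unannotated members
    still count in ``N_prot``.
    """
    n_prot = len(annotation_terms_per_protein)
    if n_prot < 2:
        raise ValueError("a cluster has at least 2 proteins")
    terms: set = set()
    for t in annotation_terms_per_protein:
        terms |= set(t)
    n_annot = len(terms)
    if n_annot == 0:
        return None
    if n_annot == 1:
        return 1.0
    return max(0.0, 1.0 - n_annot / n_prot)


@dataclass(frozen=True)
class RankSummary:
    single_taxon: bool | None  # None when no member annotated at this rank
    n_annotated_proteins: int


@dataclass(frozen=True)
class PfcScores:
    pfc_id: int
    n_prot: int
    f_hom_kegg: float | None
    f_hom_eggnog: float | None
    homogeneity_tag: str  # ok | low_08 | low_05
    taxonomy_profile: Mapping[str, RankSummary]
    mixes_domains: bool
    is_dark: bool


def taxonomy_profile(
    member_mags: Sequence[str], taxonomy_map: Mapping[str, MagTaxonomy]
) -> tuple[dict[str, RankSummary], bool]:
    """Per-rank (phylum..genus) taxonomic summary of a cluster.

    Returns the profile and whether the cluster mixes Archaea and Bacteria.
    """
    taxa = [taxonomy_map[m] for m in member_mags]
    profile: dict[str, RankSummary] = {}
    for rank in PROFILE_RANKS:
        names = [t.ranks[rank] for t in taxa if t.annotated_at(rank)]
        profile[rank] = RankSummary(
            single_taxon=(len(set(names)) == 1) if names else None,
            n_annotated_proteins=len(names),
        )
    domains = {t.ranks["domain"] for t in taxa}
    return profile, {"Archaea", "Bacteria"} <= domains


def _homogeneity_tag(f_kegg: float | None, f_egg: float | None) -> str:
    """Tag clusters scoring low in BOTH databases; tagging never excludes."""
    defined = [f for f in (f_kegg, f_egg) if f is not None]
    if not defined:
        return "ok"
    if all(f < 0.5 for f in defined) and len(defined) == 2:
        return "low_05"
    if all(f < 0.8 for f in defined) and len(defined) == 2:
        return "low_08"
    return "ok"


def classify_dark(
    f_hom_kegg: float | None,
    f_hom_eggnog: float | None,
    profile: Mapping[str, RankSummary],
) -> bool:
    """Dark = functionally unannotated in both databases AND no taxonomy
    below the phylum level (class..genus all missing)."""
    if f_hom_kegg is not None or f_hom_eggnog is not None:
        return False
    below_phylum = [r for r in PROFILE_RANKS if r != "phylum"]
    return all(profile[r].n_annotated_proteins == 0 for r in below_phylum)


def score_pfc(
    pfc_id: int,
    members: Sequence[ProteinRecord],
    taxonomy_map: Mapping[str, MagTaxonomy],
) -> PfcScores:
    f_kegg = functional_homogeneity([m.kegg_ids for m in members])
    f_egg = functional_homogeneity([m.eggnog_terms for m in members])
    profile, mixes = taxonomy_profile([m.mag_id for m in members], taxonomy_map)
    return PfcScores(
        pfc_id=pfc_id,
        n_prot=len(members),
        f_hom_kegg=f_kegg,
        f_hom_eggnog=f_egg,
        homogeneity_tag=_homogeneity_tag(f_kegg, f_egg),
        taxonomy_profile=profile,
        mixes_domains=mixes,
        is_dark=classify_dark(f_kegg, f_egg, profile),
    )


def score_partition(
    partition: PfcPartition,
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    taxonomy_map: Mapping[str, MagTaxonomy],
) -> list[PfcScores]:
    if not isinstance(records, Mapping):
        records = {r.protein_id: r for r in records}
    out = []
    for cid in sorted(partition.clusters):
        members = [records[p] for p in sorted(partition.clusters[cid])]
        out.append(score_pfc(cid, members, taxonomy_map))
    return out


def scores_to_frame(scores: Iterable[PfcScores]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {
            "pfc_id": s.pfc_id,
            "n_prot": s.n_prot,
            "f_hom_kegg": s.f_hom_kegg,
            "f_hom_eggnog": s.f_hom_eggnog,
            "homogeneity_tag": s.homogeneity_tag,
            "mixes_domains": s.mixes_domains,
            "is_dark": s.is_dark,
        }
        for rank in PROFILE_RANKS:
            rs = s.taxonomy_profile[rank]
            row[f"single_{rank}"] = rs.single_taxon
            row[f"n_annotated_{rank}"] = rs.n_annotated_proteins
        rows.append(row)
    return pd.DataFrame(rows).set_index("pfc_id")


# ---------------------------------------------------------------------------
# dark vs other abundance comparison


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum p-value, with a degeneracy flag.

    Exact null distribution when both groups have <= 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    correction.  A completely degenerate comparison (all pooled values
    identical) reports p = 1 and is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, True
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue), False


def dark_abundance_test(
    pfc_abundance: pd.DataFrame, dark_ids: Iterable[int]
) -> pd.DataFrame:
    """Per-sample comparison of dark-cluster vs other-cluster abundances.

    ``pfc_abundance`` is clusters x samples.  Returns one row per sample with
    the two-sided rank-sum p-value and group medians.
    """
    dark_ids = sorted(set(dark_ids))
    other_ids = [i for i in pfc_abundance.index if i not in set(dark_ids)]
    if len(dark_ids) < 2 or len(other_ids) < 2:
        raise ValueError("need at least 2 dark and 2 non-dark clusters")
    rows = []
    for sample in pfc_abundance.columns:
        dark = pfc_abundance.loc[dark_ids, sample].to_numpy()
        other = pfc_abundance.loc[other_ids, sample].to_numpy()
        p, degenerate = rank_sum_test(dark, other)
        rows.append(
            {
                "sample_id": sample,
                "p_value": p,
                "dark_median": float(np.median(dark)),
                "other_median": float(np.median(other)),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
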