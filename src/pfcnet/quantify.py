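"""Gene and cluster abundance quantification.

Raw mapped-read counts are normalized per gene and sample as

    abundance[g, s] = count[g, s] / (gene_length_nt[g] * total_reads[s]) * scale

with ``scale = 1e9`` by default.  The divisor is the *total sequenced* reads
of the sample (mapped + unmapped), not the mapped total: environmental
metagenomes differ wildly in sequencing depth and mapping rate, so a
TPM-style within-mapped normalization would inflate sparse samples.  Cluster
abundance is the arithmetic mean of member-protein abundances per sample.
"""

from __future__ import annotations

import pandas as pd

from .types import CountTable, PfcPartition, check_abundance_matrix


def normalize_counts(counts: CountTable, scale: float = 1e9) -> pd.DataFrame:
    """Length- and depth-normalized abundance matrix (genes x samples)."""
    lengths = counts.lengths_nt.astype(float)
    totals = counts.totals.astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"gene {bad!r}: non-positive length")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r}: non-positive total read count")
    abundance = counts.counts.div(lengths, axis=0).div(totals, axis=1) * scale
    return check_abundance_matrix(abundance)


def pfc_abundance(
    protein_abundance: pd.DataFrame, partition: PfcPartition
) -> pd.DataFrame:
    """Mean member abundance per cluster per sample (clusters x samples)."""
    missing = partition.all_proteins - set(partition.singletons) - set(
        protein_abundance.index
    )
    if missing:
        raise ValueError(
            f"cluster members missing from abundance matrix: {sorted(missing)[:5]}"
        )
    rows = {}
    for cid in sorted(partition.clusters):
        members = sorted(partition.clusters[cid])
        rows[cid] = protein_abundance.loc[members].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pfc_id"
    return check_abundance_matrix(out)
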