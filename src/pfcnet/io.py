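"""Readers and writers for the pipeline's external formats.

All tabular formats are plain TSV.  Protein FASTA headers follow the compound
convention ``mag_id|protein_id`` (delimiter configurable) as produced by
MAG-oriented gene callers.  Pairwise hits are consumed in 12-column BLAST
tabular form (outfmt 6): ``qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .types import (
    RANKS,
    UNANNOTATED,
    CountTable,
    EnvironmentTable,
    MagTaxonomy,
    PfcPartition,
    ProteinRecord,
    SimilarityHit,
)

#: text float format that round-trips IEEE doubles exactly
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# protein catalog


def _split_set(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(t for t in cell.split(",") if t)


def read_protein_catalog(
    fasta_path: str | Path,
    annotation_tsv_path: str | Path,
    taxonomy_tsv_path: str | Path,
    header_delimiter: str = "|",
) -> tuple[list[ProteinRecord], dict[str, MagTaxonomy]]:
    """Read a protein catalog: FASTA + annotation TSV + MAG taxonomy TSV.

    The annotation TSV has columns ``protein_id, gene_length_nt, kegg_ids,
    kegg_pathways, eggnog_terms`` (set-valued cells comma-separated; proteins
    absent from the table are treated as unannotated with gene length derived
    as 3 x (aa length + 1), i.e. including the stop codon).  Every referenced
    ``mag_id`` must appear in the taxonomy table.
    """
    ann = pd.read_csv(annotation_tsv_path, sep="\t", dtype=str).fillna("")
    ann_by_id: dict[str, dict] = {}
    for row in ann.to_dict("records"):
        pid = row["protein_id"]
        if pid in ann_by_id:
            raise ValueError(f"duplicate protein_id {pid!r} in annotation table")
        ann_by_id[pid] = row

    taxonomy = read_taxonomy(taxonomy_tsv_path)

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.id
        if header_delimiter not in header:
            raise ValueError(
                f"FASTA header {header!r} lacks delimiter {header_delimiter!r}"
            )
        mag_id, protein_id = header.split(header_delimiter, 1)
        if protein_id in seen:
            raise ValueError(f"duplicate protein_id {protein_id!r} in FASTA")
        seen.add(protein_id)
        if mag_id not in taxonomy:
            raise ValueError(
                f"protein {protein_id!r}: MAG {mag_id!r} missing from taxonomy table"
            )
        row = ann_by_id.get(protein_id)
        seq = str(rec.seq).upper()
        if row is not None and row.get("gene_length_nt", ""):
            length = int(row["gene_length_nt"])
        else:
            length = 3 * (len(seq) + 1)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                sequence=seq,
                mag_id=mag_id,
                gene_length_nt=length,
                kegg_ids=_split_set(row["kegg_ids"]) if row else frozenset(),
                kegg_pathways=_split_set(row["kegg_pathways"]) if row else frozenset(),
                eggnog_terms=_split_set(row["eggnog_terms"]) if row else frozenset(),
            )
        )
    return records, taxonomy


def write_protein_catalog(
    records: Iterable[ProteinRecord],
    taxonomy: Mapping[str, MagTaxonomy],
    fasta_path: str | Path,
    annotation_tsv_path: str | Path,
    taxonomy_tsv_path: str | Path,
    header_delimiter: str = "|",
) -> None:
    records = list(records)
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.mag_id}{header_delimiter}{r.protein_id}\n{r.sequence}\n")
    rows = [
        {
            "protein_id": r.protein_id,
            "gene_length_nt": r.gene_length_nt,
            "kegg_ids": ",".join(sorted(r.kegg_ids)),
            "kegg_pathways": ",".join(sorted(r.kegg_pathways)),
            "eggnog_terms": ",".join(sorted(r.eggnog_terms)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(annotation_tsv_path, sep="\t", index=False)
    write_taxonomy(taxonomy, taxonomy_tsv_path)


def read_taxonomy(path: str | Path) -> dict[str, MagTaxonomy]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNANNOTATED)
    out: dict[str, MagTaxonomy] = {}
    for row in df.to_dict("records"):
        mag_id = row["mag_id"]
        if mag_id in out:
            raise ValueError(f"duplicate mag_id {mag_id!r} in taxonomy table")
        out[mag_id] = MagTaxonomy(mag_id=mag_id, ranks={r: row[r] for r in RANKS})
    return out


def write_taxonomy(taxonomy: Mapping[str, MagTaxonomy], path: str | Path) -> None:
    rows = [
        {"mag_id": t.mag_id, **{r: t.ranks[r] for r in RANKS}}
        for t in taxonomy.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairwise hits (BLAST/DIAMOND outfmt 6)

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hits(
    tabular_path: str | Path, aa_lengths: Mapping[str, int]
) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular hits into collapsed similarity hits.

    Per-side coverage is alignment length / sequence length x 100, clamped to
    100 (gapped alignments can span more columns than either sequence).
    Self-hits are dropped; reciprocal duplicates collapse to the single hit
    with the highest percent identity per unordered pair.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    with open(tabular_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{tabular_path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                aln_len = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{tabular_path}:{lineno}: malformed row ({exc})")
            if q == s:
                continue
            for pid in (q, s):
                if pid not in aa_lengths:
                    raise ValueError(
                        f"{tabular_path}:{lineno}: unknown protein {pid!r}"
                    )
            hit = SimilarityHit(
                query_id=q,
                subject_id=s,
                pident=pident,
                cov_query=min(100.0, 100.0 * aln_len / aa_lengths[q]),
                cov_subject=min(100.0, 100.0 * aln_len / aa_lengths[s]),
            )
            key = hit.pair
            prev = best.get(key)
            if prev is None or hit.pident > prev.pident:
                best[key] = hit
    return [best[k] for k in sorted(best)]


def write_hits_outfmt6(
    hits: Iterable[SimilarityHit],
    aa_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write hits back to a minimal outfmt-6 file (positions reconstructed
    from coverages assuming alignments start at position 1)."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = round(h.cov_query * aa_lengths[h.query_id] / 100.0)
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pident:.2f}",
                        str(aln_len),
                        "0",
                        "0",
                        "1",
                        str(aln_len),
                        "1",
                        str(aln_len),
                        "1e-10",
                        "100.0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# matrices and tables


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be off by one ulp
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_count_table(
    table: CountTable,
    counts_path: str | Path,
    lengths_path: str | Path,
    totals_path: str | Path,
) -> None:
    write_matrix(table.counts, counts_path, index_label="gene_id")
    table.lengths_nt.rename("gene_length_nt").to_csv(
        lengths_path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT
    )
    table.totals.rename("total_sequenced_reads").to_csv(
        totals_path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT
    )


def read_count_table(
    counts_path: str | Path, lengths_path: str | Path, totals_path: str | Path
) -> CountTable:
    counts = read_matrix(counts_path)
    lengths = pd.read_csv(
        lengths_path, sep="\t", index_col=0, float_precision="round_trip"
    )["gene_length_nt"]
    totals = pd.read_csv(
        totals_path, sep="\t", index_col=0, float_precision="round_trip"
    )["total_sequenced_reads"]
    return CountTable(counts=counts, lengths_nt=lengths, totals=totals)


def write_env_table(env: EnvironmentTable, path: str | Path) -> None:
    """Write the environmental table plus a ``<path>.types.tsv`` sidecar
    recording each variable's declared type."""
    env.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample_id")
    types = pd.DataFrame(
        [{"variable": v, "type": "quantitative"} for v in env.quantitative]
        + [{"variable": v, "type": "qualitative"} for v in env.qualitative]
    )
    types.to_csv(_types_path(path), sep="\t", index=False)


def read_env_table(path: str | Path) -> EnvironmentTable:
    types = pd.read_csv(_types_path(path), sep="\t")
    quantitative = list(types.loc[types["type"] == "quantitative", "variable"])
    qualitative = list(types.loc[types["type"] == "qualitative", "variable"])
    data = pd.read_csv(
        path, sep="\t", index_col="sample_id", float_precision="round_trip"
    )
    data = data[quantitative + qualitative]
    for v in qualitative:
        data[v] = data[v].astype(str)
    return EnvironmentTable(
        data=data, quantitative=quantitative, qualitative=qualitative
    )


def _types_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".types.tsv")


def write_partition(
    partition: PfcPartition,
    membership_path: str | Path,
    singletons_path: str | Path,
) -> None:
    with open(membership_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "pfc_id"])
        for cid in sorted(partition.clusters):
            for pid in sorted(partition.clusters[cid]):
                w.writerow([pid, cid])
    with open(singletons_path, "w") as fh:
        fh.write("protein_id\n")
        for pid in sorted(partition.singletons):
            fh.write(pid + "\n")


def read_partition(
    membership_path: str | Path, singletons_path: str | Path
) -> PfcPartition:
    mem = pd.read_csv(membership_path, sep="\t", dtype={"protein_id": str})
    clusters: dict[int, frozenset[str]] = {}
    for cid, grp in mem.groupby("pfc_id"):
        clusters[int(cid)] = frozenset(grp["protein_id"])
    singles = pd.read_csv(singletons_path, sep="\t", dtype=str)
    return PfcPartition(
        clusters=clusters, singletons=frozenset(singles["protein_id"].dropna())
    )
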