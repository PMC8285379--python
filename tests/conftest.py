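from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pfcnet import synthetic
from pfcnet.types import MagTaxonomy, PfcPartition, ProteinRecord, RANKS, UNANNOTATED


def make_protein(pid, mag="MAG0000", seq="MKTAYIAKQR", length=33,
                 kegg=(), pathways=(), eggnog=()):
    return ProteinRecord(
        protein_id=pid, sequence=seq, mag_id=mag, gene_length_nt=length,
        kegg_ids=frozenset(kegg), kegg_pathways=frozenset(pathways),
        eggnog_terms=frozenset(eggnog),
    )


def make_taxonomy(mag_id, phylum="Proteobacteria", depth="genus"):
    """Taxonomy annotated down to ``depth`` (a rank name or 'phylum')."""
    ranks = {r: UNANNOTATED for r in RANKS}
    names = {
        "domain": "Bacteria", "phylum": phylum, "class": f"{phylum}_c",
        "order": f"{phylum}_o", "family": f"{phylum}_f", "genus": f"{phylum}_g",
    }
    for r in RANKS:
        ranks[r] = names[r]
        if r == depth:
            break
    return MagTaxonomy(mag_id=mag_id, ranks=ranks)


@pytest.fixture(scope="session")
def small_env():
    """93-sample environmental table at the study's default conditions."""
    return synthetic.generate_env(seed=7)


@pytest.fixture(scope="session")
def small_env_complete():
    return synthetic.generate_env(seed=7, complete=True)


@pytest.fixture(scope="session")
def pair_partition():
    """Ten 2-member clusters."""
    clusters = {i + 1: frozenset({f"P{2*i:03d}", f"P{2*i+1:03d}"}) for i in range(10)}
    return PfcPartition(clusters=clusters, singletons=frozenset())
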