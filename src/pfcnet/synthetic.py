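"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates, at desk scale, the structure of a MAG-derived
protein catalog and its environmental context: homologous protein families
diverged by point substitutions around the 80/80 similarity thresholds,
sparse functional annotation with unannotated fractions, MAGs truncated to
phylum-level taxonomy (planting "dark" clusters), mixed-type environmental
tables with correlated variables and missing cells, and abundance profiles
with planted environment links, pure-noise profiles, and near-constant
profiles that the near-zero-variance filter must catch.  Every generator is
a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    RANKS,
    UNANNOTATED,
    CountTable,
    EnvironmentTable,
    MagTaxonomy,
    PfcPartition,
    ProteinRecord,
)

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TruthTable:
    """Planted ground truth accompanying generated inputs."""

    planted_families: dict[str, frozenset[str]] = field(default_factory=dict)
    cluster_env_link: dict[str, dict] = field(default_factory=dict)
    planted_dark: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# protein catalog


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Point substitutions at the expected per-site rate (always to a
    different residue, so realized identity tracks 1 - divergence)."""
    out = seq.copy()
    hits = rng.random(len(seq)) < divergence
    for i in np.where(hits)[0]:
        choices = AA20[AA20 != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_catalog(
    n_mags: int = 12,
    n_families: int = 20,
    family_size_range: tuple[int, int] = (2, 6),
    divergence: float = 0.05,
    seq_length_range: tuple[int, int] = (80, 400),
    unannotated_fraction: float = 0.15,
    dark_family_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, MagTaxonomy], TruthTable]:
    """Grow protein families from random roots by point substitutions.

    A ``dark_family_fraction`` of families is fully unannotated and hosted on
    MAGs whose taxonomy stops at phylum, planting dark clusters; an
    additional ``unannotated_fraction`` of the remaining proteins lose their
    annotations at random (sparse annotation).  Members are assigned
    round-robin to MAGs within each family's MAG pool.
    """
    if not 0 <= divergence < 0.6:
        raise ValueError("divergence must lie in [0, 0.6)")
    if n_families < 1 or n_mags < 2:
        raise ValueError("need at least 1 family and 2 MAGs")
    rng = np.random.default_rng(seed)

    n_dark_fams = int(round(dark_family_fraction * n_families))
    n_dark_mags = max(2, n_mags // 4) if n_dark_fams else 0
    mag_ids = [f"MAG{m:04d}" for m in range(n_mags)]
    dark_mags = set(mag_ids[:n_dark_mags])
    taxonomy: dict[str, MagTaxonomy] = {}
    phyla = ["Proteobacteria", "Bacteroidetes", "Euryarchaeota", "Chloroflexi"]
    for m, mag in enumerate(mag_ids):
        domain = "Archaea" if phyla[m % 4] == "Euryarchaeota" else "Bacteria"
        if mag in dark_mags:
            ranks = {r: UNANNOTATED for r in RANKS}
            ranks["domain"] = domain
            ranks["phylum"] = phyla[m % 4]
        else:
            ranks = {
                "domain": domain,
                "phylum": phyla[m % 4],
                "class": f"Class_{m % 6}",
                "order": f"Order_{m % 8}",
                "family": f"Family_{m}",
                "genus": f"Genus_{m}",
            }
        taxonomy[mag] = MagTaxonomy(mag_id=mag, ranks=ranks)

    records: list[ProteinRecord] = []
    families: dict[str, frozenset[str]] = {}
    dark_families: set[str] = set()
    pid_counter = 0
    for f in range(n_families):
        fam_id = f"FAM{f:04d}"
        is_dark = f < n_dark_fams
        if is_dark:
            dark_families.add(fam_id)
        pool = sorted(dark_mags) if is_dark else [m for m in mag_ids if m not in dark_mags]
        size = int(rng.integers(family_size_range[0], family_size_range[1] + 1))
        length = int(rng.integers(seq_length_range[0], seq_length_range[1] + 1))
        root = rng.choice(AA20, size=length)
        ko = f"K{10000 + f:05d}"
        pathway = f"map{10 + f % 7:05d}"
        egg = f"nog_description_{f:04d}"
        members = []
        for i in range(size):
            pid = f"P{pid_counter:06d}"
            pid_counter += 1
            seq = "".join(_mutate(root, divergence, rng))
            annotated = (not is_dark) and rng.random() >= unannotated_fraction
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    sequence=seq,
                    mag_id=pool[i % len(pool)],
                    gene_length_nt=3 * (length + 1),
                    kegg_ids=frozenset({ko}) if annotated else frozenset(),
                    kegg_pathways=frozenset({pathway}) if annotated else frozenset(),
                    eggnog_terms=frozenset({egg}) if annotated else frozenset(),
                )
            )
            members.append(pid)
        families[fam_id] = frozenset(members)

    truth = TruthTable(
        planted_families=families, planted_dark=frozenset(dark_families)
    )
    return records, taxonomy, truth


# ---------------------------------------------------------------------------
# environmental table


def generate_env(
    n_samples: int = 93,
    n_quant: int = 24,
    n_qual: int = 4,
    qual_levels: Sequence[int] = (8, 4, 3, 2),
    corr_pairs: Sequence[tuple[int, int, float]] = ((0, 1, 0.95), (2, 3, 0.92)),
    missing_fraction: float = 0.066,
    seed: int = 0,
    complete: bool = False,
) -> EnvironmentTable:
    """Mixed-type environmental table.

    Quantitative variables are standard normal with the requested pairwise
    correlations (Cholesky construction); qualitative variables are uniform
    over their level sets (province-like factors); quantitative cells go
    missing completely at random at ``missing_fraction``.  With
    ``complete=True`` the same draw is returned without the missingness mask
    applied — the latent table that drives planted abundance signals, of
    which the measured (masked) table is a degraded view.
    """
    if not 0 <= missing_fraction <= 0.3:
        raise ValueError("missing_fraction must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    C = np.eye(n_quant)
    for i, j, rho in corr_pairs:
        C[i, j] = C[j, i] = rho
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError("requested correlation matrix is not positive definite")
    Z = rng.standard_normal((n_samples, n_quant)) @ L.T

    samples = [f"S{i:03d}" for i in range(n_samples)]
    data: dict[str, object] = {}
    quant_names = [f"env_q{i:02d}" for i in range(n_quant)]
    for i, name in enumerate(quant_names):
        data[name] = Z[:, i]
    qual_names = []
    for q in range(n_qual):
        name = f"env_f{q}"
        qual_names.append(name)
        levels = [f"{name}_L{l}" for l in range(qual_levels[q % len(qual_levels)])]
        data[name] = rng.choice(levels, size=n_samples)
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))

    if missing_fraction > 0 and not complete:
        mask = rng.random((n_samples, n_quant)) < missing_fraction
        # keep every variable observed in enough samples for k-NN imputation
        for j in range(n_quant):
            if mask[:, j].sum() > n_samples - 6:
                mask[:, j] = False
        vals = df[quant_names].to_numpy()
        vals[mask] = np.nan
        df[quant_names] = vals

    return EnvironmentTable(data=df, quantitative=quant_names, qualitative=qual_names)


# ---------------------------------------------------------------------------
# abundances and counts


@dataclass(frozen=True)
class LinkSpec:
    """Role of one cluster in the planted abundance model.

    role: "linked", "noise", or "near_constant".  For linked clusters the
    cluster-level abundance is ``base + slope * driver + offsets[level] +
    noise`` (clipped at 0), giving a signal-to-noise ratio of
    ``slope * sd(driver) / noise_sd`` for a standardized driver.
    """

    role: str
    driver: str | None = None  # quantitative driver variable
    qual_driver: str | None = None
    base: float = 5.0
    slope: float = 1.0
    qual_offsets: Mapping[str, float] | None = None
    noise_sd: float = 1.0 / 3.0


def default_link_specs(
    env: EnvironmentTable,
    n_linked: int = 20,
    n_noise: int = 20,
    n_near_constant: int = 5,
    snr: float = 3.0,
) -> dict[str, LinkSpec]:
    """Study-condition mix: linked clusters driven by rotating quantitative
    variables at the stated signal-to-noise ratio, plus pure-noise and
    near-constant clusters."""
    specs: dict[str, LinkSpec] = {}
    quant = env.quantitative
    i = 0
    for _ in range(n_linked):
        specs[f"C{i:03d}"] = LinkSpec(
            role="linked", driver=quant[i % len(quant)], noise_sd=1.0 / snr
        )
        i += 1
    for _ in range(n_noise):
        specs[f"C{i:03d}"] = LinkSpec(role="noise")
        i += 1
    for _ in range(n_near_constant):
        specs[f"C{i:03d}"] = LinkSpec(role="near_constant")
        i += 1
    return specs


def generate_abundances(
    partition: PfcPartition,
    env: EnvironmentTable,
    link_spec: Mapping[str, LinkSpec] | None = None,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Protein-level abundance matrix realizing the planted cluster roles.

    Cluster ids in ``link_spec`` are matched positionally to partition
    clusters (spec key order = cluster id order).  The cluster-level target
    is distributed to member proteins with multiplicative jitter normalized
    to mean 1 within the cluster, so the per-cluster mean recovers the target
    exactly.
    """
    rng = np.random.default_rng(seed)
    samples = env.sample_ids
    n = len(samples)
    if link_spec is None:
        link_spec = default_link_specs(env)
    spec_items = list(link_spec.items())
    cluster_ids = sorted(partition.clusters)
    if len(spec_items) < len(cluster_ids):
        raise ValueError(
            f"link_spec covers {len(spec_items)} clusters, partition has {len(cluster_ids)}"
        )

    rows: dict[str, np.ndarray] = {}
    truth = TruthTable()
    for cid, (spec_name, spec) in zip(cluster_ids, spec_items):
        members = sorted(partition.clusters[cid])
        if spec.role == "linked":
            if spec.driver is not None:
                if spec.driver not in env.data.columns:
                    raise ValueError(f"driver {spec.driver!r} absent from environment")
                z = env.data[spec.driver].to_numpy(dtype=float)
                z = np.nan_to_num(z, nan=0.0)
            else:
                z = np.zeros(n)
            target = spec.base + spec.slope * z
            if spec.qual_driver is not None:
                if spec.qual_driver not in env.data.columns:
                    raise ValueError(
                        f"driver {spec.qual_driver!r} absent from environment"
                    )
                levels = env.data[spec.qual_driver].astype(str)
                offsets = spec.qual_offsets or {}
                target = target + np.array([offsets.get(l, 0.0) for l in levels])
            if spec.noise_sd > 0:
                target = target + rng.normal(0.0, spec.noise_sd, size=n)
            target = np.clip(target, 0.0, None)
            truth.cluster_env_link[str(cid)] = {
                "role": "linked",
                "driver_variables": [
                    v for v in (spec.driver, spec.qual_driver) if v
                ],
                "noise_sd": spec.noise_sd,
            }
        elif spec.role == "noise":
            target = np.exp(rng.normal(np.log(spec.base), 0.5, size=n))
            truth.cluster_env_link[str(cid)] = {"role": "noise"}
        elif spec.role == "near_constant":
            # absent from almost all samples: exact zeros survive the
            # count round-trip, unlike a nonzero constant whose per-sample
            # normalization divisors would break the ties in float
            target = np.zeros(n)
            n_odd = 3
            odd = rng.choice(n, size=n_odd, replace=False)
            target[odd] = spec.base * (0.5 * (1 + np.arange(n_odd)))
            truth.cluster_env_link[str(cid)] = {"role": "near_constant"}
        else:
            raise ValueError(f"unknown role {spec.role!r}")

        jitter = np.exp(rng.normal(0.0, jitter_sd, size=len(members)))
        jitter /= jitter.mean()  # per-cluster mean recovers the target
        for pid, j in zip(members, jitter):
            rows[pid] = target * j

    abundance = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    abundance.index.name = "protein_id"
    return abundance, truth


def generate_counts(
    abundance: pd.DataFrame,
    lengths_nt: pd.Series,
    totals: pd.Series,
    scale: float = 1e9,
    poisson_noise: bool = False,
    seed: int = 0,
) -> CountTable:
    """Invert the normalization: count = abundance * length * total / scale,
    optionally Poisson-resampled."""
    if (abundance.values < 0).any():
        raise ValueError("abundance must be non-negative")
    lengths_nt = lengths_nt.reindex(abundance.index)
    totals = totals.reindex(abundance.columns)
    expected = abundance.mul(lengths_nt, axis=0).mul(totals, axis=1) / scale
    if poisson_noise:
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(expected.to_numpy()).astype(float),
            index=abundance.index,
            columns=abundance.columns,
        )
    else:
        counts = expected
    return CountTable(counts=counts, lengths_nt=lengths_nt, totals=totals)
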