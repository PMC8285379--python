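"""End-to-end pipeline driver.

Chains the stages: (synthetic) input generation or loading -> similarity
network -> cluster extraction -> functional/taxonomic scoring -> abundance
normalization and per-cluster means -> dark-vs-other comparison ->
environmental curation -> random-forest screen -> constrained ordination.
Every stage writes its outputs as TSV under the configured output directory;
runs are byte-reproducible given the same configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import env_prep, io, ordination, quantify, scoring, screen, ssn, synthetic
from ._seeds import stage_seed
from .types import EnvironmentTable

log = logging.getLogger("pfcnet")


class PipelineError(RuntimeError):
    """Stage failure; the message names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (or synthetic parameters), thresholds,
    screen profile, ordination options, seed, output directory."""

    outdir: str = "pfcnet_out"
    seed: int = 0
    # input paths; None for any of them switches the pipeline to synthetic mode
    fasta: str | None = None
    annotations: str | None = None
    taxonomy: str | None = None
    hits: str | None = None  # None -> all-vs-all desk-scale alignment
    counts: str | None = None
    gene_lengths: str | None = None
    sample_totals: str | None = None
    environment: str | None = None
    # synthetic-mode parameters
    synthetic: dict = field(default_factory=dict)
    # SSN thresholds
    id_threshold: float = 80.0
    cov_threshold: float = 80.0
    coverage_mode: str = "both"
    # normalization
    scale: float = 1e9
    # environment curation
    prep: dict = field(default_factory=dict)
    # screen profile: "scaled" (3 repeats / 100 trees) or "paper" (10 / 500)
    screen_profile: str = "scaled"
    screen_overrides: dict = field(default_factory=dict)
    # ordination
    run_stepwise: bool = False
    n_permutations: int = 199
    ordination_set: str = "hle"  # or "linked" (R2 > 0.25 set)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _screen_config(cfg: PipelineConfig) -> screen.ScreenConfig:
    overrides = dict(cfg.screen_overrides)
    if cfg.screen_profile == "scaled":
        return screen.ScreenConfig.scaled(**overrides)
    if cfg.screen_profile == "paper":
        return screen.ScreenConfig(**overrides)
    raise ValueError(f"unknown screen_profile {cfg.screen_profile!r}")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage, writing the result bundle under ``cfg.outdir``.

    Returns a map of logical output name -> path.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.fasta is None:
            records, taxonomy, truth, counts, env = _synthesize_inputs(cfg, out, paths)
        else:
            records, taxonomy = io.read_protein_catalog(
                cfg.fasta, cfg.annotations, cfg.taxonomy
            )
            counts = io.read_count_table(cfg.counts, cfg.gene_lengths, cfg.sample_totals)
            env = io.read_env_table(cfg.environment)
        by_id = {r.protein_id: r for r in records}
        aa_lengths = {r.protein_id: len(r.sequence) for r in records}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- similarity network ----------------------------------------------
    stage = "ssn"
    try:
        if cfg.hits is not None:
            hits = io.read_hits(cfg.hits, aa_lengths)
        elif cfg.fasta is None:
            hits_path = paths.get("hits")
            if hits_path is None:
                hits = ssn.compute_all_hits(records)
            else:
                hits = io.read_hits(hits_path, aa_lengths)
        else:
            hits = ssn.compute_all_hits(records)
        graph = ssn.filter_hits(
            hits, cfg.id_threshold, cfg.cov_threshold, cfg.coverage_mode
        )
        partition = ssn.extract_pfcs(graph, by_id)
        paths["membership"] = out / "pfc_membership.tsv"
        paths["singletons"] = out / "singletons.tsv"
        io.write_partition(partition, paths["membership"], paths["singletons"])
        paths["edges"] = out / "ssn_edges.tsv"
        edges = pd.DataFrame(
            sorted((min(a, b), max(a, b), d["pident"]) for a, b, d in graph.edges(data=True)),
            columns=["protein_a", "protein_b", "pident"],
        )
        edges.to_csv(paths["edges"], sep="\t", index=False, float_format=io.FLOAT_FMT)
        log.info("ssn: %d clusters, %d singletons", len(partition), len(partition.singletons))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- scoring ----------------------------------------------------------
    stage = "scoring"
    try:
        scores = scoring.score_partition(partition, by_id, taxonomy)
        scores_df = scoring.scores_to_frame(scores)
        paths["scores"] = out / "pfc_scores.tsv"
        scores_df.to_csv(paths["scores"], sep="\t", float_format=io.FLOAT_FMT)
        dark_ids = [s.pfc_id for s in scores if s.is_dark]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- quantification ---------------------------------------------------
    stage = "quantify"
    try:
        protein_abundance = quantify.normalize_counts(counts, cfg.scale)
        pfc_abund = quantify.pfc_abundance(protein_abundance, partition)
        paths["protein_abundance"] = out / "protein_abundance.tsv"
        paths["pfc_abundance"] = out / "pfc_abundance.tsv"
        io.write_matrix(protein_abundance, paths["protein_abundance"], "protein_id")
        io.write_matrix(pfc_abund, paths["pfc_abundance"], "pfc_id")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- dark comparison --------------------------------------------------
    stage = "dark_test"
    try:
        if len(dark_ids) >= 2 and len(pfc_abund) - len(dark_ids) >= 2:
            dark_df = scoring.dark_abundance_test(pfc_abund, dark_ids)
            paths["dark_test"] = out / "dark_abundance_test.tsv"
            dark_df.to_csv(paths["dark_test"], sep="\t", float_format=io.FLOAT_FMT)
        else:
            log.info("dark_test: skipped (fewer than 2 dark or 2 other clusters)")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- environment curation ---------------------------------------------
    stage = "env_prep"
    try:
        prep_cfg = env_prep.PrepConfig(**cfg.prep)
        env_ready, removal = env_prep.prepare_environment(env, prep_cfg)
        paths["environment_prepared"] = out / "environment_prepared.tsv"
        io.write_env_table(env_ready, paths["environment_prepared"])
        paths["removal_report"] = out / "environment_removed_variables.tsv"
        removal.to_csv(paths["removal_report"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- random-forest screen ---------------------------------------------
    stage = "screen"
    try:
        scfg = _screen_config(cfg)
        results, skipped = screen.screen_many(
            pfc_abund, env_ready, scfg, seed=stage_seed(cfg.seed, "screen")
        )
        res_df = screen.results_to_frame(results)
        paths["screen"] = out / "screen_results.tsv"
        res_df.to_csv(paths["screen"], sep="\t", float_format=io.FLOAT_FMT)
        if results:
            imp = screen.aggregate_importance(results)
            paths["importance"] = out / "importance_summary.tsv"
            imp.to_csv(paths["importance"], sep="\t", float_format=io.FLOAT_FMT)
        pd.Series(skipped, name="pfc_id").to_csv(
            out / "nzv_skipped.tsv", sep="\t", index=False
        )
        paths["nzv_skipped"] = out / "nzv_skipped.tsv"
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- ordination --------------------------------------------------------
    stage = "ordination"
    try:
        wanted = {"hle"} if cfg.ordination_set == "hle" else {"hle", "linked"}
        selected = [r.pfc_id for r in results if r.category in wanted]
        if len(selected) < 2:
            selected = [r.pfc_id for r in results]
            log.warning("ordination: too few linked clusters, using all screened")
        Y = pfc_abund.loc[selected].T  # samples x clusters
        Y = Y.loc[:, Y.sum(axis=0) > 0]
        env_ord = env_ready
        if cfg.run_stepwise:
            chosen = ordination.stepwise_select(Y, env_ready)
            if chosen:
                env_ord = env_ready.subset(chosen)
            pd.Series(chosen, name="variable").to_csv(
                out / "stepwise_selected.tsv", sep="\t", index=False
            )
            paths["stepwise_selected"] = out / "stepwise_selected.tsv"
        res = ordination.fit_cca(Y, env_ord)
        res.perm_p = ordination.permutation_test(
            Y, env_ord, cfg.n_permutations, seed=stage_seed(cfg.seed, "ordination")
        )
        paths["ordination_features"] = out / "ordination_feature_scores.tsv"
        paths["ordination_sites"] = out / "ordination_site_scores.tsv"
        paths["ordination_biplot"] = out / "ordination_biplot_scores.tsv"
        io.write_matrix(res.feature_scores, paths["ordination_features"], "pfc_id")
        io.write_matrix(res.site_scores, paths["ordination_sites"], "sample_id")
        io.write_matrix(res.biplot_scores, paths["ordination_biplot"], "variable")
        summary = pd.DataFrame(
            {
                "axis": [f"CCA{i+1}" for i in range(len(res.eigenvalues))],
                "eigenvalue": res.eigenvalues,
                "proportion_total": res.proportion_explained,
            }
        )
        summary.attrs["perm_p"] = res.perm_p
        paths["ordination_summary"] = out / "ordination_summary.tsv"
        with open(paths["ordination_summary"], "w") as fh:
            fh.write(f"# constrained_inertia\t{res.constrained_inertia:.17g}\n")
            fh.write(f"# total_inertia\t{res.total_inertia:.17g}\n")
            fh.write(f"# permutation_p\t{res.perm_p:.17g}\n")
            summary.to_csv(fh, sep="\t", index=False, float_format=io.FLOAT_FMT)
        # pathway barycenters over the selected clusters
        membership = {}
        for cid in res.feature_scores.index:
            pws = set()
            for pid in partition.clusters[int(cid)]:
                pws |= by_id[pid].kegg_pathways
            if pws:
                membership[cid] = pws
        if membership:
            bary = ordination.group_barycenters(res.feature_scores, membership)
            rows = [
                {
                    "group_id": b.group_id,
                    "n_members": b.n_members,
                    **{f"mean_CCA{i+1}": v for i, v in enumerate(b.position)},
                    **{f"sd_CCA{i+1}": v for i, v in enumerate(b.spread)},
                    "below_min_size": b.below_min_size,
                }
                for b in bary
            ]
            paths["barycenters"] = out / "pathway_barycenters.tsv"
            pd.DataFrame(rows).to_csv(
                paths["barycenters"], sep="\t", index=False, float_format=io.FLOAT_FMT
            )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    return paths


def _synthesize_inputs(cfg: PipelineConfig, out: Path, paths: dict[str, Path]):
    """Generate the full input set in synthetic mode and write it to disk so
    the run is self-documenting."""
    syn = dict(cfg.synthetic)
    n_linked = syn.pop("n_linked", 20)
    n_noise = syn.pop("n_noise", 20)
    n_near_constant = syn.pop("n_near_constant", 5)
    snr = syn.pop("snr", 3.0)
    n_samples = syn.pop("n_samples", 93)
    env_kwargs = syn.pop("env", {})
    catalog_kwargs = syn.pop("catalog", {})
    if syn:
        raise ValueError(f"unknown synthetic config keys: {sorted(syn)}")
    n_families = n_linked + n_noise + n_near_constant
    catalog_kwargs.setdefault("n_families", n_families)

    records, taxonomy, truth = synthetic.generate_catalog(
        seed=stage_seed(cfg.seed, "catalog"), **catalog_kwargs
    )
    env = synthetic.generate_env(
        n_samples=n_samples, seed=stage_seed(cfg.seed, "env"), **env_kwargs
    )
    # the latent (complete) environment drives the planted biology; the
    # masked table is what the curation stage sees
    env_complete = synthetic.generate_env(
        n_samples=n_samples, seed=stage_seed(cfg.seed, "env"), complete=True,
        **env_kwargs,
    )
    # planted partition drives the abundance model (families == clusters)
    fam_ids = sorted(truth.planted_families)
    partition_like = {
        i + 1: truth.planted_families[f] for i, f in enumerate(fam_ids)
    }
    from .types import PfcPartition

    planted = PfcPartition(clusters=partition_like, singletons=frozenset())
    specs = synthetic.default_link_specs(
        env, n_linked=n_linked, n_noise=n_noise, n_near_constant=n_near_constant, snr=snr
    )
    abundance, link_truth = synthetic.generate_abundances(
        planted, env_complete, specs, seed=stage_seed(cfg.seed, "abundance")
    )
    lengths = pd.Series(
        {r.protein_id: float(r.gene_length_nt) for r in records}
    ).reindex(abundance.index)
    rng = np.random.default_rng(stage_seed(cfg.seed, "totals"))
    totals = pd.Series(
        rng.integers(5_000_000, 20_000_000, size=len(env.sample_ids)).astype(float),
        index=abundance.columns,
    )
    counts = synthetic.generate_counts(abundance, lengths, totals, cfg.scale)

    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    io.write_protein_catalog(
        records,
        taxonomy,
        inputs / "proteins.fasta",
        inputs / "annotations.tsv",
        inputs / "taxonomy.tsv",
    )
    io.write_count_table(
        counts,
        inputs / "counts.tsv",
        inputs / "gene_lengths.tsv",
        inputs / "sample_totals.tsv",
    )
    io.write_env_table(env, inputs / "environment.tsv")
    truth_rows = [
        {"cluster": k, **v} for k, v in sorted(link_truth.cluster_env_link.items())
    ]
    pd.DataFrame(truth_rows).to_csv(inputs / "truth_links.tsv", sep="\t", index=False)
    for name in (
        "proteins.fasta",
        "annotations.tsv",
        "taxonomy.tsv",
        "counts.tsv",
        "gene_lengths.tsv",
        "sample_totals.tsv",
        "environment.tsv",
    ):
        paths[f"input_{name}"] = inputs / name
    return records, taxonomy, truth, counts, env
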