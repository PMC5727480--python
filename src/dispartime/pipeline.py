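"""End-to-end pipeline: search -> calibration -> ordinations -> disparity.

Reproduces the full analysis from a discrete matrix, an optional continuous
matrix, a taxon table and outgroup ages: parsimony search rooted on the
outgroup, Bayesian node dating, the two morphospaces, raw and
ghost-corrected disparity-through-time under both metrics (eight curves),
CGS for every curve, taxic and phylogenetic diversity, diet counts and
per-axis PIC correlations.  Every output lands in one directory together
with the serialized configuration and a manifest of SHA-256 checksums, so
any run is reproducible from its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts as contrasts_mod
from . import disparity as disp
from . import io as dio
from . import ordination as ord_mod
from . import parsimony as pars
from . import timescale
from .datamodel import ContinuousMatrix, Phylogeny
from .stages import ICS_CHART_VERSION, make_bins

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dispartime")


@dataclass
class PipelineConfig:
    discrete_path: str
    taxa_path: str
    outgroup: str
    out_dir: str
    continuous_path: str | None = None
    tree_path: str | None = None  # supplied tree bypasses the search
    outgroup_ages: list = field(default_factory=list)  # [(name, age Ma), ...]
    root_max: float = 325.0
    search_replicates: int = 20
    swap: str = "SPR"
    resampling_reps: int = 0  # 0 disables node-support resampling
    resampling_p: float = 1.0 / 3.0
    calibration_draws: int = 1000
    calibration_grid: int = 500
    bins_raw: str = "five"
    bins_ghost: str = "stages"
    n_boot: int = 1000
    axes: int | None = None  # None = all positive-variance axes
    ghost: bool = True
    seed: int | None = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_scores(res: ord_mod.OrdinationResult, path: Path) -> None:
    k = res.scores.shape[1]
    df = pd.DataFrame(res.scores, index=res.taxa, columns=[f"axis{i+1}" for i in range(k)])
    df.index.name = "taxon"
    df.to_csv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2**31 - 1))  # noqa: E731

    discrete = dio.read_nexus(config.discrete_path)
    continuous = (
        dio.read_nexus(config.continuous_path) if config.continuous_path else None
    )
    if continuous is not None and not isinstance(continuous, ContinuousMatrix):
        raise TypeError("continuous_path must point to a continuous matrix")
    taxa = dio.read_taxon_table(config.taxa_path)

    # ---- parsimony -------------------------------------------------
    if config.tree_path:
        log.info("stage search: skipped, using supplied tree %s", config.tree_path)
        tree = dio.read_newick(config.tree_path)
        fit = pars.fit_indices(tree, discrete)
    else:
        log.info("stage search: %d replicates, %s", config.search_replicates, config.swap)
        res = pars.heuristic_search(
            discrete,
            continuous,
            outgroup=config.outgroup,
            n_replicates=config.search_replicates,
            swap=config.swap,
            seed=stage_seed(),
        )
        for i, t in enumerate(res.trees):
            dio.write_newick(t, out / f"mpt_{i + 1}.nwk", include_branch_lengths=False)
        tree = res.trees[0]
        fit = pars.fit_indices(tree, discrete)
        (out / "search.json").write_text(
            json.dumps(
                {"best_length": res.length, "n_mpts": len(res.trees), "swap": res.swap},
                indent=2,
            )
        )
    (out / "fit_indices.json").write_text(
        json.dumps(
            {
                "length": fit.length,
                "ci": fit.ci,
                "hi": fit.hi,
                "ri": fit.ri,
                "ri_defined": fit.ri_defined,
            },
            indent=2,
        )
    )

    if config.resampling_reps > 0 and not config.tree_path:
        support = pars.symmetric_resampling(
            discrete,
            continuous,
            tree,
            outgroup=config.outgroup,
            n_reps=config.resampling_reps,
            p_change=config.resampling_p,
            seed=stage_seed(),
        )
        rows = [
            {"split": "|".join(sorted(s)), "frequency": f}
            for s, f in sorted(support.frequencies.items(), key=lambda kv: -kv[1])
        ]
        pd.DataFrame(rows).to_csv(out / "support.csv", index=False)

    # ---- calibration ----------------------------------------------
    # the outgroup taxon roots the tree but is not part of the clade
    ingroup_tree = tree.clone()
    og_leaf = [
        l for l in ingroup_tree.tree.leaf_node_iter() if l.taxon.label == config.outgroup
    ]
    if og_leaf:
        ingroup_tree.tree.prune_taxa([og_leaf[0].taxon])
        ingroup_tree.tree.purge_taxon_namespace()
        # pruning can leave a unifurcation at the root
        ingroup_tree.tree.suppress_unifurcations()
    ingroup_taxa = [r for r in taxa if r.name != config.outgroup]
    log.info("stage calibrate: %d draws", config.calibration_draws)
    dated, posterior = timescale.calibrate_tree(
        ingroup_tree,
        ingroup_taxa,
        config.outgroup_ages,
        root_max=config.root_max,
        n_draws=config.calibration_draws,
        seed=stage_seed(),
        grid_resolution=config.calibration_grid,
    )
    dio.write_newick(dated, out / "dated.nwk")
    age_rows = [
        {"clade": "|".join(sorted(c)), "mean_age_ma": a}
        for c, a in posterior.mean_ages.items()
    ]
    pd.DataFrame(age_rows).to_csv(out / "node_ages.csv", index=False)

    # ---- ordinations ----------------------------------------------
    names = [r.name for r in ingroup_taxa]
    pca_res = pcoa_res = None
    if continuous is not None:
        cont_in = ContinuousMatrix(
            taxa=names,
            values=np.array([continuous.row(t) for t in names]),
            char_names=list(continuous.char_names),
        )
        logged = ord_mod.logratio_transform(cont_in)
        complete = ord_mod.mean_impute(logged)
        pca_res = ord_mod.pca(complete)
        _write_scores(pca_res, out / "scores_pca.csv")
    disc_in = discrete.subset_taxa(names)
    dist = ord_mod.mord(disc_in)
    pd.DataFrame(dist.values, index=names, columns=names).to_csv(out / "distance_mord.csv")
    pcoa_res = ord_mod.pcoa(dist)
    _write_scores(pcoa_res, out / "scores_pcoa.csv")
    eig = {
        "pcoa_eigenvalues": [float(v) for v in pcoa_res.eigenvalues],
        "pcoa_positive_axes": pcoa_res.n_positive_axes,
        "pcoa_negative_axes": pcoa_res.negative_axes,
    }
    if pca_res is not None:
        eig["pca_axis_variances"] = [float(v) for v in pca_res.axis_variances]
        eig["pca_positive_axes"] = pca_res.n_positive_axes
    (out / "eigenvalues.json").write_text(json.dumps(eig, indent=2))

    # ---- disparity -------------------------------------------------
    bins_raw = make_bins(config.bins_raw)
    bins_ghost = make_bins(config.bins_ghost)
    tracks = {}
    if pca_res is not None:
        tracks["continuous"] = pca_res
    tracks["discrete"] = pcoa_res
    profile_frames, cgs_report = [], {}
    for track, scores in tracks.items():
        ghost_sets = (
            disp.ghost_lineage_scores(dated, scores, bins_ghost, taxa=ingroup_taxa, axes=config.axes)
            if config.ghost
            else None
        )
        for metric in ("sov", "sor"):
            prof = disp.disparity_profile(
                scores, ingroup_taxa, bins_raw, metric=metric,
                axes=config.axes, n_boot=config.n_boot, seed=stage_seed(),
            )
            df = prof.to_frame()
            df.insert(0, "curve", f"{track}_{metric}_raw")
            profile_frames.append(df)
            try:
                res_cgs = disp.cgs_significance(
                    scores, ingroup_taxa, bins_raw, metric=metric,
                    axes=config.axes, n_boot=config.n_boot, seed=stage_seed(),
                )
                cgs_report[f"{track}_{metric}_raw"] = {
                    "cgs": res_cgs.cgs,
                    "null": res_cgs.null_expectation,
                    "p": res_cgs.p_value,
                }
            except ValueError as exc:  # too few occupied bins for a CG
                log.warning("CGS undefined for %s_%s_raw: %s", track, metric, exc)
                cgs_report[f"{track}_{metric}_raw"] = {
                    "cgs": None, "null": None, "p": None, "reason": str(exc),
                }
            if ghost_sets is not None:
                gprof = disp.disparity_profile(
                    scores, ingroup_taxa, bins_ghost, metric=metric,
                    axes=config.axes, ghost_sets=ghost_sets,
                    n_boot=config.n_boot, seed=stage_seed(),
                )
                gdf = gprof.to_frame()
                gdf.insert(0, "curve", f"{track}_{metric}_ghost")
                profile_frames.append(gdf)
                try:
                    gres = disp.cgs(gprof.values, bins_ghost)
                    cgs_report[f"{track}_{metric}_ghost"] = {
                        "cgs": gres.cgs,
                        "null": gres.null_expectation,
                        "p": None,
                    }
                except ValueError as exc:
                    log.warning("CGS undefined for %s_%s_ghost: %s", track, metric, exc)
                    cgs_report[f"{track}_{metric}_ghost"] = {
                        "cgs": None, "null": None, "p": None, "reason": str(exc),
                    }
    pd.concat(profile_frames, ignore_index=True).to_csv(out / "profiles.csv", index=False)
    (out / "cgs.json").write_text(json.dumps(cgs_report, indent=2))

    # ---- diversity and diets ---------------------------------------
    membership = disp.assign_bins(ingroup_taxa, bins_raw)
    taxic = {b: len(m) for b, m in membership.members.items()}
    phylo = disp.phylogenetic_diversity(dated, bins_ghost, taxa=ingroup_taxa)
    pd.DataFrame(
        {"bin": list(taxic), "taxic_diversity": list(taxic.values())}
    ).to_csv(out / "diversity_taxic.csv", index=False)
    pd.DataFrame(
        {"bin": list(phylo), "phylogenetic_diversity": list(phylo.values())}
    ).to_csv(out / "diversity_phylogenetic.csv", index=False)
    disp.diet_counts(ingroup_taxa, bins_raw).to_csv(out / "diet_counts.csv")

    # ---- PIC correlations ------------------------------------------
    if pca_res is not None:
        k = min(pca_res.n_positive_axes, pcoa_res.n_positive_axes)
        pic_tree = dated.clone()
        pic_tree.perturb_zero_branches()
        rows = contrasts_mod.axis_correlations(pca_res, pcoa_res, pic_tree, k=k)
        pd.DataFrame(rows).to_csv(out / "pic_correlations.csv", index=False)

    # ---- manifest ---------------------------------------------------
    manifest = {
        "ics_chart": ICS_CHART_VERSION,
        "seed": config.seed,
        "files": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
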