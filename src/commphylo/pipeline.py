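"""End-to-end analysis: from inputs (or a synthetic design) to output tables.

``run_full_analysis`` reproduces the full chronosequence workflow: per-plot
alpha diversity, within-stage pairwise beta diversity, swap-null standardized
indices under both occurrence and abundance weighting, stage-level ANOVA/SNK
summaries and t-tests of the indices against zero, and a woody/herbaceous
re-analysis of the late (woody-dominated) stages.  Everything is driven by a
single :class:`RunConfig` and a master seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .alpha import alpha_table
from .beta import beta_table, within_stage_pairs
from .community import CommunityMatrix, read_community
from .nulls import DEFAULT_N_RAND, ses_alpha, ses_beta
from .seeding import derive_seed
from .stats import summarize_stages_anova, summarize_stages_ttest
from .synthetic import SuccessionDesign, simulate_succession_dataset
from .tree import AgeConstraints, PhyloTree, bladj_calibrate, cophenetic

logger = logging.getLogger(__name__)

LATE_STAGES = (4, 5, 6)
ALPHA_METRICS = ("richness", "simpson", "faith_pd", "mpd", "mntd")
BETA_METRICS = ("jaccard", "comdist", "comdistnt")


class ConfigError(ValueError):
    """Raised for invalid run configurations."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    Either the four input paths (tree + three CSVs, optionally a calibration
    table and root age) or ``synthetic=True`` (with an optional
    :class:`SuccessionDesign`) must be provided.
    """

    tree_path: str | None = None
    calibration_path: str | None = None
    root_age: float | None = None
    community_path: str | None = None
    plot_meta_path: str | None = None
    species_meta_path: str | None = None
    synthetic: bool = False
    design: SuccessionDesign | None = None
    n_randomizations: int = DEFAULT_N_RAND
    weightings: tuple = ("occurrence", "abundance")
    lifeform_split: bool = True
    alpha_level: float = 0.05
    pd_rooted: str = "mrca"
    seed: int = 0
    outdir: str = "commphylo_results"

    def validate(self):
        if self.n_randomizations < 1:
            raise ConfigError("n_randomizations must be >= 1")
        if not 0 < self.alpha_level < 1:
            raise ConfigError("alpha_level must be in (0, 1)")
        bad = set(self.weightings) - {"occurrence", "abundance"}
        if bad:
            raise ConfigError(f"unknown weightings: {sorted(bad)}")
        if not self.synthetic:
            needed = (self.tree_path, self.community_path,
                      self.plot_meta_path, self.species_meta_path)
            if any(p is None for p in needed):
                raise ConfigError(
                    "tree, community, plot and species paths are required "
                    "unless synthetic=True")
        return self

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if payload.get("design") is not None:
            payload["design"] = dataclasses.asdict(self.design)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_inputs(config: RunConfig):
    """Resolve (tree, community) from config, simulating if requested."""
    if config.synthetic:
        return simulate_succession_dataset(config.design, seed=config.seed)
    tree = PhyloTree.read_newick(config.tree_path)
    if config.calibration_path or config.root_age is not None:
        constraints = (AgeConstraints.read(config.calibration_path)
                       if config.calibration_path else None)
        tree = bladj_calibrate(tree, constraints, root_age=config.root_age)
    cm = read_community(config.community_path, config.plot_meta_path,
                        config.species_meta_path)
    return tree, cm


def _check_species_coverage(tree: PhyloTree, cm: CommunityMatrix):
    tips = set(tree.tip_labels)
    present = set(cm.occurring_species())
    missing = sorted(present - tips)
    if missing:
        raise ValueError(f"species present in plots but absent from tree: {missing}")


def _analysis_bundle(tree, cm, dist, config: RunConfig, seed_scope: str):
    """Alpha/beta tables, SES tables and stage summaries for one matrix."""
    out = {}
    summaries = []
    for weighting in config.weightings:
        weighted = weighting == "abundance"
        at = alpha_table(cm, tree, dist, abundance_weighted=weighted,
                         pd_rooted=config.pd_rooted)
        bt = beta_table(cm, dist, abundance_weighted=weighted)
        sa = ses_alpha(cm, dist, abundance_weighted=weighted,
                       n_rand=config.n_randomizations,
                       seed=derive_seed(config.seed, seed_scope, "alpha", weighting))
        sb = None
        if within_stage_pairs(cm):
            sb = ses_beta(cm, dist, abundance_weighted=weighted,
                          n_rand=config.n_randomizations,
                          seed=derive_seed(config.seed, seed_scope, "beta", weighting))
        out[f"alpha_{weighting}"] = at
        out[f"beta_{weighting}"] = bt
        out[f"ses_alpha_{weighting}"] = sa
        if sb is not None:
            out[f"ses_beta_{weighting}"] = sb

        if weighting == "occurrence":
            for metric in ALPHA_METRICS:
                summaries.append(summarize_stages_anova(
                    at.reset_index(), metric, alpha=config.alpha_level))
            for metric in BETA_METRICS:
                if not bt.empty:
                    summaries.append(summarize_stages_anova(
                        bt, metric, alpha=config.alpha_level))
        tt = summarize_stages_ttest(sa.reset_index(), "nri",
                                    alpha=config.alpha_level)
        tt2 = summarize_stages_ttest(sa.reset_index(), "nti",
                                     alpha=config.alpha_level)
        for t in (tt, tt2):
            t["weighting"] = weighting
        ttests = [tt, tt2]
        if sb is not None:
            for metric in ("beta_nri", "beta_nti"):
                t = summarize_stages_ttest(sb, metric, alpha=config.alpha_level)
                t["weighting"] = weighting
                ttests.append(t)
        out.setdefault("_ttests", []).extend(ttests)
    out["stage_summary"] = (pd.concat(summaries, ignore_index=True)
                            if summaries else pd.DataFrame())
    out["index_ttests"] = pd.concat(out.pop("_ttests"), ignore_index=True)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete pipeline; returns the output tables and writes CSVs.

    Outputs (written under ``config.outdir``): per-plot alpha tables,
    within-stage pairwise beta tables, SES index tables for each weighting,
    stage summaries (ANOVA/SNK and t-tests), the stage-4-6 woody/herbaceous
    split re-analysis, and a JSON run manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("commphylo")
    root_logger.addHandler(log_handler)
    try:
        tree, cm = load_inputs(config)
        _check_species_coverage(tree, cm)
        dist = cophenetic(tree)
        logger.info("loaded %d plots x %d species; tree with %d tips",
                    len(cm.plots), len(cm.species), tree.n_tips)

        pairs = within_stage_pairs(cm)
        expected = {s: n * (n - 1) // 2
                    for s, n in cm.stages.value_counts().items() if n >= 2}
        got = pd.Series([p[2] for p in pairs]).value_counts().to_dict()
        assert got == expected, "within-stage pair enumeration mismatch"
        logger.info("within-stage pair counts: %s", dict(sorted(got.items())))

        results = _analysis_bundle(tree, cm, dist, config, "main")

        if config.lifeform_split:
            split_tables = []
            for life_form in ("woody", "herbaceous"):
                try:
                    sub = cm.subset(stage=LATE_STAGES, life_form=life_form)
                except Exception as e:
                    logger.warning("life-form split %s skipped: %s", life_form, e)
                    continue
                sub_res = _analysis_bundle(tree, sub, dist, config,
                                           f"split-{life_form}")
                for key in ("stage_summary", "index_ttests"):
                    t = sub_res[key].copy()
                    t["life_form"] = life_form
                    t["table"] = key
                    split_tables.append(t)
            if split_tables:
                results["lifeform_summary"] = pd.concat(split_tables,
                                                        ignore_index=True)

        for name, table in results.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.csv",
                             index=table.index.name is not None)

        manifest = {
            "package": "commphylo",
            "version": __version__,
            "seed": config.seed,
            "n_randomizations": config.n_randomizations,
            "weightings": list(config.weightings),
            "config_hash": config.config_hash(),
            "n_plots": int(len(cm.plots)),
            "n_species": int(len(cm.species)),
            "n_occurring_species": int(len(cm.occurring_species())),
            "stage_plot_counts": {int(s): int(n) for s, n
                                  in cm.stages.value_counts().sort_index().items()},
            "within_stage_pairs": {int(s): int(n) for s, n in sorted(got.items())},
            "tables": sorted(k for k, v in results.items()
                             if isinstance(v, pd.DataFrame)),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True) + "\n")
        results["manifest"] = manifest
        return results
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()
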