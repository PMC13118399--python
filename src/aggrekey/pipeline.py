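"""End-to-end orchestration: aggregates -> letters -> ordination ->
network -> keystone selection -> path model, with a reproducibility
manifest.

Every stage is a pure function of (inputs, config, seed); the global seed
is expanded into independent per-stage substreams so a stage's randomness
does not depend on execution order.  A run writes its artifact set plus
``manifest.json`` (config hash, seed, per-file SHA-256); re-running into a
directory whose manifest matches the config hash and seed verifies the
cached files instead of rewriting them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .aggregate_metrics import contrast_table, sample_metrics, treatment_summary
from .community_ecology import (AbundanceTable, bray_curtis, dominant_genera,
                                pcoa, permanova, rarefy, remove_amf_from_its)
from .cooccurrence_network import (CoocNetwork, build_network, detect_modules,
                                   major_modules, module_abundance)
from .group_stats import anova_duncan
from .io_config import ResultBundle, RunConfig, StudyDesign, write_results
from .keystone_selection import (crucial_genera, importance_ranking,
                                 keystone_genera, keystone_modules)
from .plspm import PathSpec, effects, fit_plspm, pc1_scores

logger = logging.getLogger("aggrekey")

DEFAULT_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "intercrop_vs_mono": (reference.GROUP1 + reference.GROUP2, ("MM",)),
    "group1_vs_group2": (reference.GROUP1, reference.GROUP2),
    "group1_vs_mono": (reference.GROUP1, ("MM",)),
    "group2_vs_mono": (reference.GROUP2, ("MM",)),
}


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    metrics: pd.DataFrame
    summary: pd.DataFrame
    letters: pd.DataFrame
    contrasts: pd.DataFrame
    ordination: dict[str, dict[str, Any]] = field(default_factory=dict)
    network: CoocNetwork | None = None
    modules: pd.Series | None = None
    major: tuple[str, ...] = ()
    module_profiles: pd.DataFrame | None = None
    keystone: pd.DataFrame | None = None
    keystone_members: dict[str, list[str]] = field(default_factory=dict)
    rankings: dict[str, Any] = field(default_factory=dict)
    crucial: list[str] = field(default_factory=list)
    crucial_table: pd.DataFrame | None = None
    pc1: Any = None
    path_model: Any = None
    effects: pd.DataFrame | None = None
    manifest: dict[str, Any] | None = None


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _letters_table(metrics: pd.DataFrame, design: StudyDesign,
                   alpha: float) -> pd.DataFrame:
    rows = {}
    for col in metrics.columns:
        la = anova_duncan(metrics[col], design, alpha=alpha)
        rows[col] = la.letters
    out = pd.DataFrame(rows)
    out.index.name = "treatment"
    return out


def run_tables_only(profiles, design: StudyDesign,
                    config: RunConfig | None = None,
                    contrasts: Mapping[str, tuple[Sequence[str], Sequence[str]]]
                    | None = None) -> PipelineResult:
    """Aggregate metrics, Duncan letters and group contrasts without any
    microbiome input."""
    config = (config or RunConfig()).validate()
    if not design.samples:
        raise ValueError("empty design")
    metrics = sample_metrics(profiles)
    summary = treatment_summary(metrics, design)
    letters = _letters_table(metrics, design, config.duncan_alpha)
    usable = {name: ab for name, ab in (contrasts or DEFAULT_CONTRASTS).items()
              if all(t in design.treatments for t in list(ab[0]) + list(ab[1]))}
    ctr = contrast_table(metrics, design, usable) if usable else pd.DataFrame()
    return PipelineResult(config=config, metrics=metrics, summary=summary,
                          letters=letters, contrasts=ctr)


def run_all(tables: Mapping[str, AbundanceTable], profiles,
            design: StudyDesign, config: RunConfig | None = None,
            taxonomy: Mapping[str, str] | None = None,
            out_dir: str | Path | None = None,
            contrasts=None) -> PipelineResult:
    """Execute the full analysis chain on genus tables + aggregate profiles.

    ``tables`` maps kingdom -> counts (or relative) AbundanceTable; the
    fungal table may still contain Glomeromycota genera if ``taxonomy`` is
    given.  Stages: aggregate metrics, ANOVA letters, ordination/PERMANOVA,
    co-occurrence network + modules, keystone modules/genera, importance
    ranking, PC1 + PLS path model, artifact writing.
    """
    config = (config or RunConfig()).validate()
    rng_rarefy, rng_permanova, rng_rf = _substreams(config.seed, 3)

    stage = "aggregate_metrics"
    try:
        result = run_tables_only(profiles, design, config, contrasts)

        stage = "community_preprocessing"
        prepared: dict[str, AbundanceTable] = {}
        for kingdom, table in tables.items():
            if kingdom == "nonamf" and taxonomy is not None:
                table = remove_amf_from_its(table, dict(taxonomy))
            if not table.is_relative:
                table = rarefy(table, config.rarefaction_depth, rng_rarefy)
            rel = table.to_relative()
            keep = dominant_genera(rel, config.dominant_cutoff)
            prepared[kingdom] = rel.subset_genera(keep)

        stage = "ordination"
        for kingdom, rel in prepared.items():
            d = bray_curtis(rel)
            ord_res = pcoa(d)
            f, p = permanova(d, design, config.permanova_permutations,
                             rng_permanova)
            result.ordination[kingdom] = {
                "pcoa": ord_res, "pseudo_F": f, "p": p}

        stage = "network"
        network = build_network(list(prepared.values()), config)
        modules = detect_modules(network, config.walktrap_steps)
        major = major_modules(network, config.major_module_fraction)
        profiles_z = module_abundance(network)
        result.network, result.modules = network, modules
        result.major = major
        result.module_profiles = profiles_z

        stage = "keystone"
        response_cols = [c for c in result.metrics.columns
                         if c.startswith("c_pct:")]
        responses = result.metrics.loc[list(profiles_z.columns), response_cols]
        keystone_df = keystone_modules(profiles_z, responses, major,
                                       config.keystone_alpha)
        result.keystone = keystone_df
        flagged = list(keystone_df.index[keystone_df["keystone"]])
        candidates: list[str] = []
        for mod in flagged:
            members = modules.index[modules == mod]
            chosen = keystone_genera(members, network, design,
                                     config.keystone_abundance_fraction,
                                     config.duncan_alpha)
            result.keystone_members[mod] = chosen
            candidates.extend(chosen)

        stage = "importance"
        if len(candidates) >= 2:
            for col in response_cols:
                result.rankings[col] = importance_ranking(
                    network, candidates, responses[col],
                    n_trees=config.rf_trees,
                    n_permutations=config.rf_permutations, seed=rng_rf)
            result.crucial, result.crucial_table = crucial_genera(
                result.rankings, config.rf_alpha)
        else:
            logger.warning("fewer than 2 keystone genera; skipping ranking")

        stage = "plspm"
        if len(result.crucial) >= 2:
            pc = pc1_scores(network.abundances, result.crucial)
            result.pc1 = pc
            scheme = config.scheme
            ind = result.metrics.loc[list(pc.scores.index)].copy()
            ind["pc1"] = pc.scores
            blocks = {
                "microbes": ("pc1",),
                "mass": tuple(f"mass_pct:{l}" for l in scheme.labels),
                "conc": tuple(f"soc_conc:{l}" for l in scheme.labels),
                "cdist": tuple(f"c_pct:{l}" for l in scheme.labels),
                "mwd": ("mwd",),
            }
            inner = (("microbes", "mass"), ("microbes", "conc"),
                     ("microbes", "cdist"), ("mass", "cdist"),
                     ("conc", "cdist"), ("mass", "mwd"), ("cdist", "mwd"))
            spec = PathSpec(blocks=blocks, inner=inner)
            model = fit_plspm(ind, spec, scheme=config.plspm_scheme,
                              tol=config.plspm_tol,
                              max_iter=config.plspm_max_iter)
            result.path_model = model
            result.effects = effects(model)
        else:
            logger.warning("fewer than 2 crucial genera; skipping path model")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if out_dir is not None:
        _emit(result, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _emit(result: PipelineResult, out_dir: Path) -> None:
    cfg = result.config
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        cached = json.loads(manifest_path.read_text())
        if (cached.get("config_hash") == cfg.config_hash()
                and cached.get("seed") == cfg.seed
                and all(Path(out_dir, name).exists()
                        and _sha256(Path(out_dir, name)) == digest
                        for name, digest in cached.get("files", {}).items())):
            logger.info("manifest matches config+seed; reusing cached outputs")
            result.manifest = cached
            return

    modules_df = None
    if result.modules is not None:
        modules_df = result.modules.to_frame()
        modules_df["major"] = modules_df["module"].isin(result.major)
    plspm_payload = None
    if result.path_model is not None:
        m = result.path_model
        plspm_payload = {
            "blocks": {k: list(v) for k, v in m.spec.blocks.items()},
            "path_coefficients": {
                t: {s: float(m.path_matrix.loc[t, s])
                    for s in m.path_matrix.columns
                    if m.path_matrix.loc[t, s] != 0}
                for t in m.path_matrix.index},
            "r_squared": m.r_squared,
            "gof": m.gof,
            "effects": result.effects.to_dict(orient="records"),
            "pc1_variance_explained": (result.pc1.variance_explained
                                       if result.pc1 else None),
            "iterations": m.iterations,
        }
    ordination_frames = {}
    for kingdom, entry in result.ordination.items():
        ord_res = entry["pcoa"]
        k = min(5, ord_res.coordinates.shape[1])
        coords = ord_res.coordinates.iloc[:, :k].copy()
        coords.index.name = "sample_id"
        coords.attrs["variance_explained"] = tuple(
            ord_res.proportion_explained[:k])
        ordination_frames[kingdom] = coords

    extra = {
        "major_modules": list(result.major),
        "keystone_members": result.keystone_members,
        "crucial_genera": result.crucial,
        "permanova": {k: {"pseudo_F": v["pseudo_F"], "p": v["p"]}
                      for k, v in result.ordination.items()},
        "variance_explained": {k: v.variance_explained
                               for k, v in result.rankings.items()},
    }
    bundle = ResultBundle(config=cfg, metrics=result.metrics,
                          summary=_flatten(result.summary),
                          letters=result.letters, contrasts=result.contrasts,
                          edges=(result.network.edges
                                 if result.network is not None else None),
                          modules=modules_df, keystone=result.keystone,
                          crucial=result.crucial_table, plspm=plspm_payload,
                          ordination=ordination_frames, extra=extra)
    written = write_results(out_dir, bundle)
    if result.network is not None and len(result.network.edges):
        from .cooccurrence_network import write_graphml
        gml = out_dir / "network.graphml"
        write_graphml(result.network, gml)
        written["network.graphml"] = gml
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "files": {name: _sha256(path)
                          for name, path in sorted(written.items())}}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    result.manifest = manifest


def _flatten(summary: pd.DataFrame) -> pd.DataFrame:
    out = summary.copy()
    out.columns = [f"{metric}:{stat}" for metric, stat in out.columns]
    return out
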