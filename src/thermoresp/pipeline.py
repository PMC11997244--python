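"""End-to-end pipeline orchestration with a single config and a manifest.

Stages run in order — io, filtering, genesets, bootstrap, models, thermal
(optional) — each wrapped so a failure surfaces with the stage name.  All
randomness flows from the single config seed through named substreams, and
re-running with the same inputs and seed reproduces the output tables byte
for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bootstrap as bt
from . import filtering as flt
from . import genesets as gs
from . import io_tables as iot
from . import models as mdl
from . import thermal as th
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)

_PARAM_RANGES = {
    "tpm_threshold": (0.0, np.inf),
    "min_genes": (1, 10_000),
    "subset_fraction": (0.0, 1.0),
    "n_resamples": (1, 1_000_000),
    "presence_min": (1, 10_000),
    "expressed_min": (1, 10_000),
    "pseudocount": (0.0, np.inf),
    "grid_step": (1e-6, 10.0),
    "smoothing_window": (1, 1_000),
}


@dataclass
class PipelineConfig:
    """Paths plus the analysis parameters (defaults follow the study design)."""

    metadata: str | None = None
    expression: dict[str, str] = field(default_factory=dict)  # species -> path
    annotations: dict[str, str] = field(default_factory=dict)
    orthogroups: str | None = None
    traces: str | None = None
    out_dir: str | None = None
    seed: int | None = None
    tpm_threshold: float = 10.0
    min_genes: int = 10
    subset_fraction: float = 0.75
    n_resamples: int = 1000
    presence_min: int = 15
    expressed_min: int = 12
    pseudocount: float = 0.5
    df_mode: str = "residual"
    go_mode: str = "per_species"
    grid_step: float = 0.1
    smoothing_window: int = 5
    bootstrap_replace: bool = False

    def params(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("metadata", "expression", "annotations", "orthogroups", "traces", "out_dir"):
            d.pop(k)
        return d


def validate_config(raw: dict | str | Path) -> PipelineConfig:
    """Build a validated config from a dict or a YAML file.

    Defaults are injected for missing keys; unknown keys are rejected and all
    type/range violations are reported at once.
    """
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown config key '{k}'" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for key, (lo, hi) in _PARAM_RANGES.items():
        val = getattr(cfg, key)
        try:
            ok = lo <= float(val) <= hi
        except (TypeError, ValueError):
            ok = False
        if not ok:
            errors.append(f"{key}={val!r} outside [{lo}, {hi}]")
    if cfg.df_mode not in ("residual", "normal"):
        errors.append(f"df_mode={cfg.df_mode!r} not in (residual, normal)")
    if cfg.go_mode not in ("per_species", "total"):
        errors.append(f"go_mode={cfg.go_mode!r} not in (per_species, total)")
    if cfg.n_resamples > 0 and cfg.seed is None:
        errors.append("seed is required when n_resamples > 0")
    if errors:
        raise ConfigError("; ".join(errors))
    if cfg.tpm_threshold == 0:
        log.warning("tpm_threshold=0: expression filter disabled")
    return cfg


@dataclass
class PipelineResult:
    retained: dict
    fold_changes: pd.DataFrame
    catalog: gs.GeneSetCatalog
    go_expression: pd.DataFrame
    go_fc: pd.DataFrame
    og_expression: pd.DataFrame
    treatment_summary: pd.DataFrame
    biome_summary: pd.DataFrame
    lmm_results: pd.DataFrame
    biome_results: pd.DataFrame
    thermal_traits: pd.DataFrame | None = None
    acclimation: pd.DataFrame | None = None
    acclimation_results: pd.DataFrame | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("models")
def _fit_models(cfg, metadata_df, go_expr, og_expr, go_fc):
    lmm_rows = []
    for source in (go_expr, og_expr):
        if source is None or source.empty:
            continue
        for set_id, grp in source.groupby("set_id", sort=True):
            try:
                res = mdl.fit_treatment_lmm(grp, set_id=set_id, df_mode=cfg.df_mode)
            except Exception as exc:
                log.warning("LMM for %s failed: %s", set_id, exc)
                continue
            lmm_rows.extend(res.to_rows())
    lmm = pd.DataFrame(lmm_rows)

    biome_rows = []
    biome = metadata_df.drop_duplicates("species_id").set_index("species_id")["biome"]
    for (set_id, contrast), grp in go_fc.groupby(["set_id", "contrast"], sort=True):
        fc = grp.set_index("species_id")["estimate"]
        try:
            res = mdl.fit_biome_lm(fc, biome.reindex(fc.index), set_id, contrast)
        except Exception as exc:
            log.warning("biome model for %s/%s failed: %s", set_id, contrast, exc)
            continue
        biome_rows.append(
            {
                "set_id": set_id, "contrast": contrast,
                "r_squared": res.r_squared, "p_value": res.p_value,
                "n_species": res.n_species,
                "flagged_biomes": ";".join(res.flagged_biomes),
            }
        )
    return lmm, pd.DataFrame(biome_rows)


@_stage("thermal")
def _fit_thermal(cfg, traces, go_fc, catalog):
    traits = th.trace_traits(traces, cfg.grid_step, cfg.smoothing_window)
    deltas = th.acclimation_deltas(traits).set_index("species_id")
    rows = []
    pairing = {
        "Tcrit_hot": "HvsN", "Tmax_hot": "HvsN",
        "Tcrit_cold": "CvsN", "Tmax_cold": "CvsN",
    }
    for trait, contrast in pairing.items():
        for set_id, grp in go_fc[go_fc["contrast"] == contrast].groupby("set_id", sort=True):
            fc = grp.set_index("species_id")["estimate"]
            min_n = catalog.go_min_count(set_id) if set_id in catalog.go_members else None
            try:
                res = mdl.fit_acclimation_lm(
                    deltas[trait], fc, trait=trait, set_id=set_id, min_n=min_n
                )
            except Exception as exc:
                log.warning("acclimation model %s/%s failed: %s", trait, set_id, exc)
                continue
            rows.append(
                {
                    "trait": trait, "set_id": set_id, "slope": res.slope,
                    "t": res.t, "p_value": res.p_value,
                    "adj_r_squared": res.adj_r_squared,
                    "n_species": res.n_species, "min_n": res.min_n,
                    "fc_median": res.fc_median, "fc_min": res.fc_min,
                    "fc_max": res.fc_max,
                }
            )
    return traits, deltas.reset_index(), pd.DataFrame(rows)


def run_pipeline_objects(
    cfg: PipelineConfig,
    metadata: list[iot.LibraryRecord],
    expression: dict[str, iot.SpeciesExpression],
    annotations: dict[str, iot.AnnotationTable],
    orthogroups: dict | None = None,
    traces: list | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory objects (the library entry point)."""
    meta_df = iot.metadata_frame(metadata)

    @_stage("filtering")
    def do_filter():
        retained = {
            sp: flt.filter_low_expression(expression[sp], cfg.tpm_threshold)
            for sp in sorted(expression)
        }
        fc = flt.fold_change_table(expression, retained, metadata, cfg.pseudocount)
        return retained, fc

    retained, fold_changes = do_filter()

    @_stage("genesets")
    def do_catalog():
        return gs.build_catalog(
            annotations, retained, orthogroups,
            min_genes=cfg.min_genes, subset_fraction=cfg.subset_fraction,
            presence_min=cfg.presence_min, expressed_min=cfg.expressed_min,
            go_mode=cfg.go_mode,
        )

    catalog = do_catalog()

    @_stage("bootstrap")
    def do_bootstrap():
        go_expr = bt.go_expression_per_library(
            expression, catalog, meta_df, cfg.n_resamples, cfg.seed or 0,
            cfg.bootstrap_replace,
        )
        go_fc = bt.go_fc_per_species(
            fold_changes, catalog, cfg.n_resamples, cfg.seed or 0,
            cfg.bootstrap_replace,
        )
        og_expr = bt.orthogroup_expression(expression, catalog, meta_df)
        tsum = bt.treatment_group_summary(go_expr, meta_df, "treatment")
        bsum = bt.treatment_group_summary(go_fc, meta_df, "biome_treatment")
        return go_expr, go_fc, og_expr, tsum, bsum

    go_expr, go_fc, og_expr, tsum, bsum = do_bootstrap()
    lmm, biome_results = _fit_models(cfg, meta_df, go_expr, og_expr, go_fc)

    result = PipelineResult(
        retained=retained, fold_changes=fold_changes, catalog=catalog,
        go_expression=go_expr, go_fc=go_fc, og_expression=og_expr,
        treatment_summary=tsum, biome_summary=bsum,
        lmm_results=lmm, biome_results=biome_results,
    )
    if traces:
        result.thermal_traits, result.acclimation, result.acclimation_results = (
            _fit_thermal(cfg, traces, go_fc, catalog)
        )
    else:
        log.info("no fluorescence traces given: acclimation stage skipped")
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every tidy result table under ``out_dir`` (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    retained_rows = []
    for sp in sorted(result.retained):
        r = result.retained[sp]
        retained_rows.append(
            pd.DataFrame(
                {"species_id": sp, "gene_id": r.gene_ids,
                 "mean_tpm": r.mean_tpm.to_numpy()}
            )
        )
    iot.write_tsv(pd.concat(retained_rows, ignore_index=True), out / "retained_genes.tsv")
    iot.write_tsv(result.fold_changes, out / "fold_changes.tsv")
    iot.write_tsv(result.catalog.table(), out / "geneset_catalog.tsv")
    iot.write_tsv(result.go_expression, out / "go_expression_boot.tsv")
    iot.write_tsv(result.go_fc, out / "go_fc_boot.tsv")
    iot.write_tsv(result.og_expression, out / "orthogroup_expression.tsv")
    iot.write_tsv(result.treatment_summary, out / "treatment_summary.tsv")
    iot.write_tsv(result.biome_summary, out / "biome_fc_summary.tsv")
    iot.write_tsv(result.lmm_results, out / "lmm_results.tsv")
    iot.write_tsv(result.biome_results, out / "biome_results.tsv")
    if result.thermal_traits is not None:
        iot.write_tsv(result.thermal_traits, out / "thermal_traits.tsv")
        iot.write_tsv(result.acclimation, out / "acclimation_deltas.tsv")
        iot.write_tsv(result.acclimation_results, out / "acclimation_results.tsv")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs per config, run, write, manifest."""
    if cfg.metadata is None:
        raise ConfigError("config needs a metadata path")

    @_stage("io")
    def do_io():
        metadata = iot.read_metadata(cfg.metadata)
        species_ids = sorted({r.species_id for r in metadata})
        expression = {
            sp: iot.read_expression_auto(path, sp)
            for sp, path in sorted(cfg.expression.items())
        }
        missing = [sp for sp in species_ids if sp not in expression]
        if missing:
            raise ConfigError(f"no expression input for species {missing}")
        annotations = {
            sp: iot.read_trinotate_go(path, sp)
            for sp, path in sorted(cfg.annotations.items())
        }
        orthogroups = (
            iot.read_orthogroups(cfg.orthogroups, species_ids)
            if cfg.orthogroups else None
        )
        traces = th.read_traces(cfg.traces) if cfg.traces else None
        return metadata, expression, annotations, orthogroups, traces

    metadata, expression, annotations, orthogroups, traces = do_io()
    result = run_pipeline_objects(
        cfg, metadata, expression, annotations, orthogroups, traces
    )
    if cfg.out_dir:
        write_results(result, cfg.out_dir)
        inputs = {"metadata": cfg.metadata}
        inputs.update({f"expression:{sp}": p for sp, p in cfg.expression.items()})
        inputs.update({f"annotations:{sp}": p for sp, p in cfg.annotations.items()})
        if cfg.orthogroups:
            inputs["orthogroups"] = cfg.orthogroups
        if cfg.traces:
            inputs["traces"] = cfg.traces
        iot.write_manifest(cfg.out_dir, inputs, cfg.params(), cfg.seed)
    return result
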