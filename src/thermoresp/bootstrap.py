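"""The bootstrapped-median gene-set expression statistic.

For each retained GO term and species, ``n_resamples`` random gene subsets of
the catalog's fixed subset size are drawn without replacement from the term's
member genes; the median of each subset is taken and the resampled medians
are averaged.  The fixed subset size (75% of the smallest cross-species
member count) makes the estimate comparable across species with unequal
annotation depth.  Estimates are computed per individual library on the TPM
scale and per species on the log2 fold-change scale.

Randomness is fully deterministic: each (term, species) pair gets its own RNG
substream derived from the master seed, so results do not depend on the order
in which terms are processed.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .errors import ValidationError, ZeroVarianceError
from .genesets import GeneSetCatalog
from .io_tables import LibraryRecord, SpeciesExpression, metadata_frame


def substream_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by (master seed, *keys)."""
    label = "\x1f".join(str(k) for k in keys).encode()
    digest = hashlib.blake2b(label, digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")])
    )


def _subset_indices(
    rng: np.random.Generator, n_values: int, size: int, n_resamples: int,
    replace: bool,
) -> np.ndarray:
    """(n_resamples, size) index matrix of random subsets."""
    if replace:
        return rng.integers(0, n_values, size=(n_resamples, size))
    if size == n_values:
        # every subset is the full set; no need to randomise
        return np.tile(np.arange(n_values), (n_resamples, 1))
    keys = rng.random((n_resamples, n_values))
    return np.argsort(keys, axis=1)[:, :size]


def bootstrap_median(
    values,
    subset_size: int,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    replace: bool = False,
) -> float:
    """Mean over resamples of the median of a random fixed-size gene subset.

    Subsets are drawn without replacement by default (subsampling); a
    with-replacement mode is available for sensitivity analysis.
    """
    vals = np.asarray(values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("bootstrap_median requires finite values")
    if not 1 <= subset_size <= vals.size:
        raise ValidationError(
            f"subset_size {subset_size} infeasible for {vals.size} values"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = _subset_indices(rng, vals.size, subset_size, n_resamples, replace)
    medians = np.median(vals[idx], axis=1)
    return float(medians.mean())


def go_expression_per_library(
    expr_by_species: dict[str, SpeciesExpression],
    catalog: GeneSetCatalog,
    metadata: list[LibraryRecord] | pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Bootstrapped median TPM per retained GO term x individual library.

    The same gene subsets (drawn per term x species) are applied to every
    library of the species, so between-library differences reflect expression
    only, not resampling noise.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    rows = []
    for term in sorted(catalog.go_members):
        size = catalog.go_subset_size[term]
        for sp in catalog.species_universe:
            genes = catalog.go_members[term].get(sp, [])
            if not genes:
                continue
            expr = expr_by_species[sp]
            missing = [g for g in genes if g not in expr.tpm.index]
            if missing:
                raise ValidationError(
                    f"term {term}: {len(missing)} member genes missing from "
                    f"{sp} expression matrix (e.g. {missing[0]})"
                )
            mat = expr.tpm.loc[genes].to_numpy(float)  # genes x libraries
            rng = substream_rng(seed, "go_expr", term, sp)
            idx = _subset_indices(rng, len(genes), size, n_resamples, replace)
            # (n_resamples, size, n_libraries) -> median over genes -> mean
            medians = np.median(mat[idx, :], axis=1)
            estimates = medians.mean(axis=0)
            for lib, est in zip(expr.tpm.columns, estimates):
                rows.append(
                    {
                        "set_id": term,
                        "species_id": sp,
                        "library_id": lib,
                        "estimate": float(est),
                        "subset_size": size,
                        "n_resamples": n_resamples,
                        "seed": seed,
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.merge(meta[["library_id", "treatment", "biome"]], on="library_id")
    return out


def go_fc_per_species(
    fold_changes: pd.DataFrame,
    catalog: GeneSetCatalog,
    n_resamples: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Bootstrapped median log2 FC per retained GO term x species x contrast.

    ``fold_changes`` is the tidy table (species_id, gene_id, contrast,
    log2fc).  Genes with missing FC (possible only with pseudocount 0) are
    excluded; the subset size is capped at the available pool, never below 1.
    """
    fc_idx = {
        key: grp.set_index("gene_id")["log2fc"]
        for key, grp in fold_changes.groupby(["species_id", "contrast"])
    }
    rows = []
    for term in sorted(catalog.go_members):
        size = catalog.go_subset_size[term]
        for sp in catalog.species_universe:
            genes = catalog.go_members[term].get(sp, [])
            if not genes:
                continue
            for contrast in ("HvsN", "CvsN"):
                series = fc_idx.get((sp, contrast))
                if series is None:
                    raise ValidationError(f"no fold changes for {sp}/{contrast}")
                vals = series.reindex(genes).to_numpy(float)
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    raise ValidationError(
                        f"term {term}: no finite FC values for {sp}/{contrast}"
                    )
                eff_size = min(size, vals.size)
                rng = substream_rng(seed, "go_fc", term, sp, contrast)
                est = bootstrap_median(
                    vals, eff_size, n_resamples, rng=rng, replace=replace
                )
                rows.append(
                    {
                        "set_id": term,
                        "species_id": sp,
                        "contrast": contrast,
                        "estimate": est,
                        "subset_size": eff_size,
                        "n_resamples": n_resamples,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def orthogroup_expression(
    expr_by_species: dict[str, SpeciesExpression],
    catalog: GeneSetCatalog,
    metadata: list[LibraryRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean TPM of member genes per retained orthogroup x library.

    The mean (not the bootstrapped median) is used because many orthogroups
    carry a single gene per species.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    rows = []
    for og in sorted(catalog.og_members):
        for sp, genes in sorted(catalog.og_members[og].items()):
            expr = expr_by_species[sp]
            missing = [g for g in genes if g not in expr.tpm.index]
            if missing:
                raise ValidationError(
                    f"orthogroup {og}: member genes missing from {sp} matrix"
                )
            means = expr.tpm.loc[genes].mean(axis=0)
            for lib, est in means.items():
                rows.append(
                    {
                        "set_id": og,
                        "species_id": sp,
                        "library_id": lib,
                        "estimate": float(est),
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.merge(meta[["library_id", "treatment", "biome"]], on="library_id")
    return out


def zscale(values) -> np.ndarray:
    """Scale to mean 0, SD 1 (sample SD, n-1); constant input is an error."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ZeroVarianceError("zscale needs at least 2 values")
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("zscale of a zero-variance vector")
    return (vals - vals.mean()) / sd


def treatment_group_summary(
    summaries: pd.DataFrame,
    metadata: list[LibraryRecord] | pd.DataFrame,
    grouping: str = "treatment",
) -> pd.DataFrame:
    """Mean +/- SE per group of bootstrapped estimates.

    ``grouping='treatment'`` summarises library-level estimates per set_id x
    treatment.  ``grouping='biome_treatment'`` summarises species-level FC
    estimates per set_id x contrast x biome (the unit is the species).
    Single-member groups report SE as missing; empty groups are omitted.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    df = summaries.copy()
    if grouping == "treatment":
        if "treatment" not in df.columns:
            df = df.merge(meta[["library_id", "treatment"]], on="library_id")
        keys = ["set_id", "treatment"]
    elif grouping == "biome_treatment":
        if "biome" not in df.columns:
            biome = meta.drop_duplicates("species_id")[["species_id", "biome"]]
            df = df.merge(biome, on="species_id")
        keys = ["set_id", "contrast", "biome"]
    else:
        raise ValidationError(f"unknown grouping '{grouping}'")
    out = (
        df.groupby(keys, sort=True)["estimate"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "se"] = np.nan
    return out.drop(columns="sd")
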