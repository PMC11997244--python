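"""Expression filtering and log2 fold-change contrasts.

Genes are retained when their mean TPM across *all* of a species' libraries
(treatments pooled) meets the threshold, default 10 TPM inclusive.  Treatment
means are unweighted arithmetic means over the libraries of each species x
treatment cell (TPM is already depth-normalised, so no library weighting).
Fold changes are log2 of the treatment/control mean ratio with a small
pseudocount guarding zero means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import LibraryRecord, SpeciesExpression, metadata_frame

#: contrast name -> numerator treatment (denominator is always control)
CONTRASTS = {"HvsN": "hot", "CvsN": "cold"}


@dataclass
class RetainedGeneSet:
    """Genes of one species passing the mean-TPM expression filter."""

    species_id: str
    gene_ids: list[str]
    threshold: float
    mean_tpm: pd.Series  # retained genes only


def filter_low_expression(
    expr: SpeciesExpression, threshold: float = 10.0
) -> RetainedGeneSet:
    """Retain genes with mean TPM >= ``threshold`` over all libraries.

    The boundary is inclusive; an empty retained set is a hard error because
    the species is then unusable downstream.
    """
    if expr.tpm.shape[1] == 0:
        raise ValidationError(f"{expr.species_id}: no libraries")
    means = expr.tpm.mean(axis=1)
    keep = means[means >= threshold]
    if keep.empty:
        raise ValidationError(
            f"{expr.species_id}: no genes with mean TPM >= {threshold}"
        )
    return RetainedGeneSet(
        species_id=expr.species_id,
        gene_ids=list(keep.index),
        threshold=float(threshold),
        mean_tpm=keep,
    )


def treatment_means(
    expr: SpeciesExpression,
    retained: RetainedGeneSet,
    metadata: list[LibraryRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean TPM per retained gene for each treatment of one species.

    Single-library treatments return that library's value; a treatment with
    zero libraries for the species is a hard error.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    meta = meta[meta["species_id"] == expr.species_id]
    cols = {}
    for treatment in ("control", "cold", "hot"):
        libs = [
            l for l in meta.loc[meta["treatment"] == treatment, "library_id"]
            if l in expr.tpm.columns
        ]
        if not libs:
            raise ValidationError(
                f"{expr.species_id}: no libraries for treatment '{treatment}'"
            )
        cols[treatment] = expr.tpm.loc[retained.gene_ids, libs].mean(axis=1)
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return out


def log2_fold_change(
    means: pd.DataFrame, contrast: str, pseudocount: float = 0.5
) -> pd.Series:
    """log2((mean_treatment + pc) / (mean_control + pc)) per retained gene.

    Antisymmetric under swapping numerator and denominator.  With
    ``pseudocount=0`` a zero mean produces +/-inf, which is propagated as
    missing (NaN) so downstream medians exclude it.
    """
    if contrast not in CONTRASTS:
        raise ValidationError(f"unknown contrast '{contrast}'")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    num = means[CONTRASTS[contrast]].to_numpy(float) + pseudocount
    den = means["control"].to_numpy(float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num) - np.log2(den)
    fc[~np.isfinite(fc)] = np.nan
    return pd.Series(fc, index=means.index, name=contrast)


def fold_change_table(
    expr_by_species: dict[str, SpeciesExpression],
    retained_by_species: dict[str, RetainedGeneSet],
    metadata: list[LibraryRecord],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Tidy fold-change table over all species and both contrasts."""
    rows = []
    for sp in sorted(expr_by_species):
        means = treatment_means(expr_by_species[sp], retained_by_species[sp], metadata)
        for contrast in ("HvsN", "CvsN"):
            fc = log2_fold_change(means, contrast, pseudocount)
            rows.append(
                pd.DataFrame(
                    {
                        "species_id": sp,
                        "gene_id": fc.index,
                        "contrast": contrast,
                        "log2fc": fc.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
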