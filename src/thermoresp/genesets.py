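"""GO-term and orthogroup gene-set construction and retention rules.

A biological-process GO term is comparable across species only if every
species contributes enough annotated, expressed genes: the default rule keeps
a term when its per-species member count (post expression filter) is at least
``min_genes`` in *every* species.  The bootstrap subset size for a retained
term is 75% of the minimum member count across species, rounded half-up and
floored at 1 — this is what makes the median statistic comparable across
species with different annotation depths.

Orthogroups pass a two-stage filter: present (>= 1 gene, before the
expression filter) in at least ``presence_min`` species, then expressed
(>= 1 retained gene) in at least ``expressed_min`` species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .filtering import RetainedGeneSet
from .io_tables import AnnotationTable

log = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Retained GO terms and orthogroups with members and subset sizes."""

    species_universe: list[str]
    go_members: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    go_subset_size: dict[str, int] = field(default_factory=dict)
    go_counts: pd.DataFrame | None = None  # all candidate terms x species
    og_members: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    og_table: pd.DataFrame | None = None  # og, n_present, n_expressed, retained

    def go_min_count(self, term: str) -> int:
        return min(len(v) for v in self.go_members[term].values())

    def table(self) -> pd.DataFrame:
        """Tidy catalog table (set_id, set_type, species_id, n_members, ...)."""
        rows = []
        for term in sorted(self.go_members):
            for sp in self.species_universe:
                rows.append(
                    {
                        "set_id": term,
                        "set_type": "go",
                        "species_id": sp,
                        "n_members": len(self.go_members[term].get(sp, [])),
                        "retained": True,
                        "subset_size": self.go_subset_size[term],
                    }
                )
        for og in sorted(self.og_members):
            for sp, genes in sorted(self.og_members[og].items()):
                rows.append(
                    {
                        "set_id": og,
                        "set_type": "orthogroup",
                        "species_id": sp,
                        "n_members": len(genes),
                        "retained": True,
                        "subset_size": 0,
                    }
                )
        return pd.DataFrame(rows)


def build_go_sets(
    annotations: Mapping[str, AnnotationTable],
    retained: Mapping[str, RetainedGeneSet],
) -> dict[str, dict[str, list[str]]]:
    """Raw GO -> {species -> retained annotated genes} membership.

    A gene contributes to every GO term it carries; membership is restricted
    to genes passing the expression filter.
    """
    missing = set(annotations) - set(retained)
    if missing:
        raise ValidationError(
            f"species with annotations but no retained gene set: {sorted(missing)}"
        )
    raw: dict[str, dict[str, list[str]]] = {}
    for sp in sorted(annotations):
        keep = set(retained[sp].gene_ids)
        for gene in sorted(annotations[sp].go):
            if gene not in keep:
                continue
            for term in annotations[sp].go[gene]:
                raw.setdefault(term, {}).setdefault(sp, []).append(gene)
    return raw


def subset_size(counts: Iterable[int], fraction: float = 0.75) -> int:
    """Bootstrap subset size: round-half-up(fraction x min count), >= 1."""
    mn = min(counts)
    return max(1, math.floor(fraction * mn + 0.5))


def retain_go_terms(
    raw: Mapping[str, Mapping[str, Sequence[str]]],
    species_universe: Sequence[str],
    min_genes: int = 10,
    subset_fraction: float = 0.75,
    mode: str = "per_species",
) -> tuple[dict[str, dict[str, list[str]]], dict[str, int], pd.DataFrame]:
    """Apply the GO retention rule and compute subset sizes.

    ``mode='per_species'`` (default): keep a term only when its member count
    is >= ``min_genes`` in every species of the universe.  ``mode='total'``
    keeps a term when the summed count is >= ``min_genes`` (alternative
    reading; subset sizes are then still bounded by the smallest non-zero
    per-species count).
    """
    if not species_universe:
        raise ValidationError("empty species universe")
    universe = list(species_universe)
    counts = pd.DataFrame(
        {
            term: {sp: len(raw[term].get(sp, [])) for sp in universe}
            for term in sorted(raw)
        }
    ).T
    counts.index.name = "set_id"
    members: dict[str, dict[str, list[str]]] = {}
    sizes: dict[str, int] = {}
    for term in counts.index:
        per_sp = counts.loc[term]
        if mode == "per_species":
            ok = int(per_sp.min()) >= min_genes
        elif mode == "total":
            ok = int(per_sp.sum()) >= min_genes and (per_sp > 0).all()
        else:
            raise ValidationError(f"unknown GO retention mode '{mode}'")
        if not ok:
            log.info("GO term %s dropped (counts %s)", term, per_sp.to_dict())
            continue
        members[term] = {sp: list(raw[term][sp]) for sp in universe}
        sizes[term] = subset_size(per_sp.tolist(), subset_fraction)
        log.info("GO term %s retained (subset size %d)", term, sizes[term])
    if not members:
        raise ValidationError("no GO terms retained")
    return members, sizes, counts


def retain_orthogroups(
    og_map: Mapping[str, Mapping[str, Sequence[str]]],
    retained: Mapping[str, RetainedGeneSet],
    presence_min: int = 15,
    expressed_min: int = 12,
) -> tuple[dict[str, dict[str, list[str]]], pd.DataFrame]:
    """Two-stage orthogroup filter: presence, then post-filter expression."""
    keep_sets = {sp: set(r.gene_ids) for sp, r in retained.items()}
    rows = []
    members: dict[str, dict[str, list[str]]] = {}
    for og in sorted(og_map):
        present = {sp: list(genes) for sp, genes in og_map[og].items() if genes}
        n_present = len(present)
        expressed = {
            sp: [g for g in genes if g in keep_sets.get(sp, set())]
            for sp, genes in present.items()
        }
        expressed = {sp: g for sp, g in expressed.items() if g}
        n_expressed = len(expressed)
        ok = n_present >= presence_min and n_expressed >= expressed_min
        rows.append(
            {
                "set_id": og,
                "n_present": n_present,
                "n_expressed": n_expressed,
                "retained": ok,
            }
        )
        if ok:
            members[og] = expressed
            log.info("orthogroup %s retained (%d/%d species)", og, n_expressed, n_present)
        else:
            log.info(
                "orthogroup %s dropped (present %d, expressed %d)",
                og, n_present, n_expressed,
            )
    table = pd.DataFrame(rows)
    if not members:
        log.warning("no orthogroups retained")
    return members, table


def build_catalog(
    annotations: Mapping[str, AnnotationTable],
    retained: Mapping[str, RetainedGeneSet],
    orthogroups: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    min_genes: int = 10,
    subset_fraction: float = 0.75,
    presence_min: int = 15,
    expressed_min: int = 12,
    go_mode: str = "per_species",
) -> GeneSetCatalog:
    """Convenience wrapper producing a complete :class:`GeneSetCatalog`."""
    universe = sorted(retained)
    raw = build_go_sets(annotations, retained)
    go_members, sizes, counts = retain_go_terms(
        raw, universe, min_genes, subset_fraction, go_mode
    )
    cat = GeneSetCatalog(
        species_universe=universe,
        go_members=go_members,
        go_subset_size=sizes,
        go_counts=counts,
    )
    if orthogroups is not None:
        cat.og_members, cat.og_table = retain_orthogroups(
            orthogroups, retained, presence_min, expressed_min
        )
    return cat
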