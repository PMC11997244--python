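"""Readers and writers for the external table formats.

The pipeline consumes the output formats of an upstream de novo
transcriptomics workflow: RSEM ``.genes.results`` gene-expression tables (or a
generic gene x library TPM matrix), Trinotate-style annotation reports for
gene -> GO links, an OrthoFinder-style ``Orthogroups.tsv``, a library metadata
CSV and long-format fluorescence-trace CSVs.  Everything is parsed into plain
dataclasses around pandas objects; parsers either succeed completely or raise
a typed :class:`~thermoresp.errors.FormatError`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

TREATMENTS = ("control", "cold", "hot")
BIOMES = ("arid", "alpine", "temperate")
#: accepted synonyms, folded to canonical enum values
_BIOME_ALIASES = {"temp": "temperate"}
_TREATMENT_ALIASES = {"neutral": "control"}

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class LibraryRecord:
    """One sequencing library: the unit of observation for expression models."""

    library_id: str
    species_id: str
    treatment: str
    biome: str


@dataclass
class SpeciesExpression:
    """Gene x library TPM matrix for one species' de novo gene set."""

    species_id: str
    tpm: pd.DataFrame  # index: gene_id, columns: library_id

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            dups = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene_ids in {self.species_id}: {dups[:5]}"
            )
        vals = self.tpm.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValidationError(
                f"negative or non-finite TPM values in {self.species_id}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class AnnotationTable:
    """Per-species gene -> GO(biological process) annotation."""

    species_id: str
    go: dict[str, set[str]]  # gene_id -> set of GO ids (BP branch only)
    orthogroup: dict[str, str] = field(default_factory=dict)


def metadata_frame(records: Sequence[LibraryRecord]) -> pd.DataFrame:
    """Tidy frame view of library metadata, indexed by library_id."""
    return pd.DataFrame(
        [(r.library_id, r.species_id, r.treatment, r.biome) for r in records],
        columns=["library_id", "species_id", "treatment", "biome"],
    )


def read_metadata(path: str | Path) -> list[LibraryRecord]:
    """Read the library metadata CSV.

    Requires columns library_id, species_id, treatment, biome.  Treatment and
    biome values are case-folded to the canonical enums; duplicate library ids
    and unknown enum values are hard errors naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"library_id", "species_id", "treatment", "biome"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata {path}: missing columns {sorted(missing)}")
    records: list[LibraryRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        lib = str(row["library_id"]).strip()
        if lib in seen:
            raise FormatError(f"metadata {path}: duplicate library_id '{lib}'")
        seen.add(lib)
        treatment = str(row["treatment"]).strip().lower()
        treatment = _TREATMENT_ALIASES.get(treatment, treatment)
        if treatment not in TREATMENTS:
            raise FormatError(
                f"metadata {path} row {i}: unknown treatment '{row['treatment']}'"
            )
        biome = str(row["biome"]).strip().lower()
        biome = _BIOME_ALIASES.get(biome, biome)
        if biome not in BIOMES:
            raise FormatError(
                f"metadata {path} row {i}: unknown biome '{row['biome']}'"
            )
        records.append(
            LibraryRecord(lib, str(row["species_id"]).strip(), treatment, biome)
        )
    return records


def read_rsem_genes(path: str | Path, library_id: str) -> pd.Series:
    """Read one RSEM ``.genes.results`` file into a gene -> TPM series."""
    df = pd.read_csv(path, sep="\t")
    if "TPM" not in df.columns or "gene_id" not in df.columns:
        raise FormatError(f"{path}: not an RSEM genes.results file (need gene_id, TPM)")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: gene_id '{dup}' repeated")
    tpm = pd.to_numeric(df["TPM"], errors="coerce")
    if tpm.isna().any():
        raise FormatError(f"{path}: non-numeric TPM values")
    if (tpm < 0).any():
        bad = df.loc[tpm < 0, "gene_id"].iloc[0]
        raise FormatError(f"{path}: negative TPM for gene '{bad}'")
    out = pd.Series(tpm.to_numpy(float), index=df["gene_id"].astype(str), name=library_id)
    out.index.name = "gene_id"
    return out


def assemble_species_matrix(
    species_id: str,
    vectors: Mapping[str, pd.Series],
    library_order: Sequence[str] | None = None,
) -> SpeciesExpression:
    """Column-bind per-library TPM vectors that share one gene universe."""
    if not vectors:
        raise ValidationError(f"{species_id}: no libraries to assemble")
    order = list(library_order) if library_order is not None else list(vectors)
    first = set(vectors[order[0]].index)
    for lib in order[1:]:
        other = set(vectors[lib].index)
        if other != first:
            n_diff = len(first.symmetric_difference(other))
            raise ValidationError(
                f"{species_id}: library '{lib}' gene universe differs from "
                f"'{order[0]}' by {n_diff} genes"
            )
    mat = pd.concat([vectors[lib].rename(lib) for lib in order], axis=1)
    mat.index.name = "gene_id"
    return SpeciesExpression(species_id, mat)


def _parse_go_cell(cell: str, where: str) -> set[str]:
    """Extract biological_process GO ids from one Trinotate-style cell.

    Entries are backtick-separated ``GO:nnnnnnn^branch^name`` triples;
    malformed entries are skipped with a logged warning, never fatal.
    """
    terms: set[str] = set()
    if not cell or cell == ".":
        return terms
    for entry in cell.split("`"):
        parts = entry.split("^")
        if len(parts) < 2 or not _GO_RE.match(parts[0]):
            log.warning("malformed GO entry %r in %s; skipped", entry, where)
            continue
        if parts[1] == "biological_process":
            terms.add(parts[0])
    return terms


def read_trinotate_go(path: str | Path, species_id: str) -> AnnotationTable:
    """Extract gene -> GO(BP) links from a Trinotate-style report TSV.

    The union is taken over every GO-bearing column (BLASTX- and Pfam-derived)
    and over rows (transcripts) of the same gene.  Only biological_process
    entries are retained; a file yielding zero BP annotations is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col = None
    for cand in ("#gene_id", "gene_id"):
        if cand in df.columns:
            gene_col = cand
            break
    if gene_col is None:
        gene_col = df.columns[0]
    go_cols = [c for c in df.columns if "gene_ontology" in c.lower()]
    if not go_cols:
        raise FormatError(f"{path}: no gene_ontology columns found")
    go: dict[str, set[str]] = {}
    for i, row in df.iterrows():
        gene = str(row[gene_col]).strip()
        terms: set[str] = set()
        for c in go_cols:
            terms |= _parse_go_cell(str(row[c]), f"{path}:{i}")
        if terms:
            go.setdefault(gene, set()).update(terms)
    if not go:
        raise FormatError(
            f"{path}: no biological_process annotations for {species_id}"
        )
    return AnnotationTable(species_id=species_id, go=go)


def read_orthogroups(
    path: str | Path, known_species: Iterable[str] | None = None
) -> dict[str, dict[str, list[str]]]:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    Returns orthogroup -> {species -> gene list}; species with empty cells are
    absent from that orthogroup's mapping (a fully empty row maps to ``{}``).
    Columns for species not in ``known_species`` are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    og_col = df.columns[0]
    species_cols = list(df.columns[1:])
    if known_species is not None:
        known = set(known_species)
        unknown = [c for c in species_cols if c not in known]
        for c in unknown:
            log.warning("orthogroups %s: unknown species column '%s' ignored", path, c)
        species_cols = [c for c in species_cols if c in known]
    out: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = str(row[og_col]).strip()
        if og in out:
            raise FormatError(f"{path}: duplicate orthogroup id '{og}'")
        members: dict[str, list[str]] = {}
        for sp in species_cols:
            cell = str(row[sp]).strip()
            if cell:
                genes = [g.strip() for g in cell.split(",") if g.strip()]
                if genes:
                    members[sp] = genes
        out[og] = members
    return out


def read_generic_tpm(path: str | Path, species_id: str) -> SpeciesExpression:
    """Read a generic gene x library TPM TSV (gene_id + one column per library)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: generic TPM table needs a gene_id column")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: gene_id '{dup}' repeated")
    mat = df.set_index("gene_id")
    mat.index = mat.index.astype(str)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values ({exc})") from exc
    return SpeciesExpression(species_id, mat)


def write_generic_tpm(expr: SpeciesExpression, path: str | Path) -> None:
    df = expr.tpm.reset_index()
    df = df.rename(columns={df.columns[0]: "gene_id"})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression_auto(path: str | Path, species_id: str) -> SpeciesExpression:
    """Auto-detect dialect: RSEM single-library file vs generic TPM matrix.

    A header carrying ``TPM`` together with RSEM bookkeeping columns
    (expected_count / effective_length) marks the RSEM dialect; anything else
    with a gene_id column is treated as a generic matrix.  A directory is read
    as one ``<library_id>.genes.results`` per library.
    """
    p = Path(path)
    if p.is_dir():
        vectors = {
            f.name.replace(".genes.results", ""): read_rsem_genes(
                f, f.name.replace(".genes.results", "")
            )
            for f in sorted(p.glob("*.genes.results"))
        }
        if not vectors:
            raise FormatError(f"{p}: no .genes.results files found")
        return assemble_species_matrix(species_id, vectors)
    header = pd.read_csv(p, sep="\t", nrows=0).columns
    if "TPM" in header and ({"expected_count", "effective_length"} & set(header)):
        lib = p.name.removesuffix(".genes.results") if p.name.endswith(
            ".genes.results"
        ) else p.stem
        vec = read_rsem_genes(p, lib)
        return assemble_species_matrix(species_id, {vec.name: vec})
    return read_generic_tpm(p, species_id)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table deterministically (stable byte output)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    inputs: Mapping[str, str | Path],
    params: Mapping[str, object],
    seed: int | None,
) -> Path:
    """Write a JSON provenance manifest (input checksums, parameters, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(inputs.items())
            if p is not None and Path(p).is_file()
        },
        "parameters": {k: params[k] for k in sorted(params)},
        "seed": seed,
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
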