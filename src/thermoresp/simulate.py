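"""Synthetic multi-species RNA-seq and fluorescence-trace generator.

Generates a complete study bundle with known ground truth: 20 species from
three biomes with the unbalanced library design of the real experiment (188
libraries, including single-library treatment arms), lognormal TPM with
species- and library-level random effects, planted treatment effects on the
log2 scale for designated GO terms (so a planted beta equals the expected
log2 fold change), orthogroups engineered to pass or fail the two-stage
presence/expression filter exactly, and two-segment fluorescence traces with
known breakpoints linked to the planted expression responses.

Gene-level model, for gene g of species s in library l with treatment tau:

    log2 TPM = mu_g + u_s + v_l + beta_{g,tau,biome(s)} + eps_{g,l}

with u_s ~ N(0, sigma_species^2) a species intercept shared by all genes,
v_l ~ N(0, sigma_library^2) a library effect shared within a library (this
is what survives the median-over-genes summary, so the planted summary-level
ICC is sigma_sp^2 / (sigma_sp^2 + sigma_lib^2)), and eps iid gene-level
noise.  Genes below the expression filter are planted with low baselines;
any gene whose realised mean TPM strays into the filter margin is
deterministically rescaled (a per-gene row scaling, which leaves fold
changes and z-scores unchanged) so the planted retained counts are exact.

Everything is deterministic given the config seed, via named RNG substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import substream_rng
from .errors import ConfigError
from .genesets import subset_size
from .io_tables import (
    AnnotationTable,
    LibraryRecord,
    SpeciesExpression,
    write_generic_tpm,
)
from .thermal import FluorescenceTrace


@dataclass
class SpeciesDesign:
    species_id: str
    biome: str
    n_control: int
    n_cold: int
    n_hot: int
    n_expressed: int  # genes planted above the TPM filter
    n_low: int  # genes planted below the TPM filter


@dataclass
class GoTermDesign:
    term: str
    base_count: int  # minimum per-species member count
    count_jitter: int = 5  # per-species extra members, uniform 0..jitter
    beta_hot: dict[str, float] | float = 0.0  # per biome or scalar
    beta_cold: dict[str, float] | float = 0.0
    species_jitter_sd: float = 0.0  # per-species jitter on the effects
    distractor: str | None = None  # None | 'low_count' | 'absent'

    def responsive(self) -> bool:
        def any_nonzero(b):
            return any(v != 0 for v in b.values()) if isinstance(b, dict) else b != 0

        return (
            any_nonzero(self.beta_hot)
            or any_nonzero(self.beta_cold)
            or self.species_jitter_sd > 0
        )


@dataclass
class ThermalDesign:
    tcrit_hot_mean: float = 45.0
    tcrit_hot_sd: float = 2.0
    tmax_hot_offset: float = 8.0
    tcrit_cold_mean: float = -8.0
    tcrit_cold_sd: float = 1.5
    tmax_cold_offset: float = -6.0
    # acclimation deltas linked to the designated acclim terms' species FCs
    delta_hot_intercept: float = 1.0
    delta_hot_slope: float = 1.8
    delta_hot_noise_sd: float = 0.8
    delta_cold_intercept: float = 1.0
    delta_cold_slope: float = -2.0
    delta_cold_noise_sd: float = 0.8
    plant_jitter_sd: float = 0.3
    heating_rate: float = 30.0  # degC per hour, 20 -> 65
    cooling_rate: float = 15.0  # degC per hour, 20 -> -25
    log_interval_s: float = 5.0


@dataclass
class SimulationConfig:
    seed: int = 0
    species: list[SpeciesDesign] = field(default_factory=list)
    go_terms: list[GoTermDesign] = field(default_factory=list)
    # orthogroup structure counts and the quorums they are engineered around
    n_og_qualifying: int = 78
    n_og_present_only: int = 142
    n_og_minor: int = 80
    og_presence_quorum: int = 15
    og_expressed_quorum: int = 12
    n_responsive_og: int = 2
    og_beta_hot: float = 0.9
    # variance components (log2 units)
    sigma_species: float = 0.5
    sigma_library: float = 0.553
    sigma_gene: float = 0.6
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.2
    low_log2_mean: float = 0.5
    low_log2_sd: float = 0.8
    tpm_threshold: float = 10.0
    thermal: ThermalDesign = field(default_factory=ThermalDesign)
    n_plants: int = 5
    trace_noise_sd: float = 0.01

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("no species in simulation config")
        for sp in self.species:
            for n in (sp.n_control, sp.n_cold, sp.n_hot, sp.n_expressed, sp.n_low):
                if n < 1:
                    raise ConfigError(f"{sp.species_id}: all counts must be >= 1")
        for t in self.go_terms:
            if t.distractor is None and t.base_count < 10:
                raise ConfigError(
                    f"{t.term}: qualifying terms need base_count >= 10"
                )
            for b in (t.beta_hot, t.beta_cold):
                vals = b.values() if isinstance(b, dict) else [b]
                if not all(np.isfinite(list(vals))):
                    raise ConfigError(f"{t.term}: non-finite effect size")
        if self.n_plants < 1:
            raise ConfigError("n_plants must be >= 1")


@dataclass
class GroundTruth:
    retained_per_species: dict[str, int]
    qualifying_terms: list[str]
    subset_sizes: dict[str, int]
    term_effects: dict[str, dict]
    true_icc: float
    sigma_species: float
    sigma_library: float
    n_og_present_quorum: int
    n_og_expressed_quorum: int
    og_quorums: tuple[int, int]
    responsive_ogs: dict[str, float]
    species_beta_hot_acclim: dict[str, float]
    species_beta_cold_acclim: dict[str, float]
    thermal_baselines: dict[str, dict[str, float]]
    thermal_deltas: dict[str, dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SimBundle:
    config: SimulationConfig
    metadata: list[LibraryRecord]
    expression: dict[str, SpeciesExpression]
    annotations: dict[str, AnnotationTable]
    orthogroups: dict[str, dict[str, list[str]]]
    traces: list  # of FluorescenceTrace
    truth: GroundTruth


# the real study's unbalanced design: (biome, n_control, n_cold, n_hot,
# retained transcripts) for each of the 20 species
_STUDY_DESIGN = [
    ("alpine", 2, 2, 3, 11900),
    ("alpine", 4, 4, 4, 12361),
    ("alpine", 4, 3, 4, 12106),
    ("alpine", 4, 4, 4, 12895),
    ("alpine", 1, 1, 2, 12300),
    ("alpine", 4, 3, 4, 13192),
    ("alpine", 4, 3, 4, 10853),
    ("arid", 1, 1, 1, 12843),
    ("arid", 1, 1, 1, 12317),
    ("arid", 3, 3, 3, 12852),
    ("arid", 4, 4, 4, 11405),
    ("arid", 3, 4, 4, 12228),
    ("arid", 2, 2, 1, 11523),
    ("arid", 4, 4, 4, 10949),
    ("temperate", 4, 3, 4, 12767),
    ("temperate", 3, 4, 4, 10572),
    ("temperate", 4, 4, 4, 13293),
    ("temperate", 3, 4, 4, 11762),
    ("temperate", 3, 3, 3, 11571),
    ("temperate", 3, 4, 4, 10177),
]

# archetypal planted responses (index, effects); biome-differential effects
# mirror weaker heat responses in arid species and weaker cold responses in
# alpine species
_ACCLIM_HOT_TERM = "GO:1000013"
_ACCLIM_COLD_TERM = "GO:1000014"


def _default_terms(n_terms: int = 134, rng: np.random.Generator | None = None):
    """Default GO catalog: responsive archetypes + null terms + distractors."""
    rng = rng or np.random.default_rng(12345)
    terms: list[GoTermDesign] = []

    def t(i, **kw):
        return GoTermDesign(term=f"GO:1{i:06d}", **kw)

    # strong heat-up (protein-folding / ROS / heat-response archetypes)
    for i in range(1, 4):
        terms.append(t(i, base_count=int(rng.integers(20, 60)), beta_hot=1.0))
    # moderate heat-up
    for i in range(4, 6):
        terms.append(t(i, base_count=int(rng.integers(15, 40)), beta_hot=0.6))
    # cold-up (chitin / ethylene archetypes)
    for i in range(6, 8):
        terms.append(t(i, base_count=int(rng.integers(12, 30)), beta_cold=0.5))
    # cold-down (photosynthesis / DNA-replication archetypes)
    for i in range(8, 11):
        terms.append(t(i, base_count=int(rng.integers(20, 70)), beta_cold=-0.7))
    # biome-differential heat response (weaker in arid)
    for i in range(11, 12):
        terms.append(
            t(i, base_count=int(rng.integers(14, 40)),
              beta_hot={"arid": 0.25, "alpine": 0.9, "temperate": 0.9})
        )
    # biome-differential cold response (weaker in alpine)
    for i in range(12, 13):
        terms.append(
            t(i, base_count=int(rng.integers(14, 40)),
              beta_cold={"alpine": -0.15, "arid": -0.7, "temperate": -0.7})
        )
    # acclimation-linked terms with per-species effect jitter
    terms.append(
        t(13, base_count=26, beta_hot=0.7, species_jitter_sd=0.6)
    )
    terms.append(
        t(14, base_count=20, beta_cold=-0.5, species_jitter_sd=0.6)
    )
    # null terms up to n_terms, with a spread of set sizes incl. the minimum
    i = 15
    while len(terms) < n_terms:
        base = 10 if i % 17 == 0 else int(rng.integers(10, 100))
        terms.append(t(i, base_count=base))
        i += 1
    # distractors: must fail retention
    terms.append(
        GoTermDesign(term="GO:1900001", base_count=20, distractor="low_count")
    )
    terms.append(
        GoTermDesign(term="GO:1900002", base_count=15, distractor="absent")
    )
    return terms


def default_config(seed: int = 0) -> SimulationConfig:
    """Full-scale study conditions: 20 species, 188 libraries, 134 GO terms,
    220 orthogroups present in >= 15 species of which 78 expressed in >= 12."""
    species = [
        SpeciesDesign(
            species_id=f"sp{i + 1:02d}",
            biome=biome,
            n_control=nc, n_cold=ncold, n_hot=nh,
            n_expressed=n_ret,
            n_low=4000,
        )
        for i, (biome, nc, ncold, nh, n_ret) in enumerate(_STUDY_DESIGN)
    ]
    return SimulationConfig(seed=seed, species=species, go_terms=_default_terms())


def small_config(seed: int = 0) -> SimulationConfig:
    """Reduced-scale bundle for fast tests: 6 species (2 per biome), small
    gene universes, 10 qualifying terms, orthogroup quorums 5/4."""
    biomes = ["alpine", "alpine", "arid", "arid", "temperate", "temperate"]
    designs = [(2, 2, 2), (3, 2, 3), (1, 1, 1), (3, 3, 3), (2, 3, 2), (3, 3, 3)]
    species = [
        SpeciesDesign(
            species_id=f"sp{i + 1:02d}", biome=b,
            n_control=d[0], n_cold=d[1], n_hot=d[2],
            n_expressed=300, n_low=120,
        )
        for i, (b, d) in enumerate(zip(biomes, designs))
    ]
    terms = [
        GoTermDesign("GO:1000001", base_count=15, beta_hot=1.0),
        GoTermDesign("GO:1000002", base_count=12, beta_hot=0.6),
        GoTermDesign("GO:1000003", base_count=12, beta_cold=0.5),
        GoTermDesign("GO:1000004", base_count=14, beta_cold=-0.7),
        GoTermDesign("GO:1000005", base_count=12,
                     beta_hot={"arid": 0.2, "alpine": 0.9, "temperate": 0.9}),
        GoTermDesign(_ACCLIM_HOT_TERM, base_count=14, beta_hot=0.7,
                     species_jitter_sd=0.6),
        GoTermDesign(_ACCLIM_COLD_TERM, base_count=12, beta_cold=-0.5,
                     species_jitter_sd=0.6),
        GoTermDesign("GO:1000008", base_count=10),
        GoTermDesign("GO:1000009", base_count=20),
        GoTermDesign("GO:1000010", base_count=11),
        GoTermDesign("GO:1900001", base_count=15, distractor="low_count"),
        GoTermDesign("GO:1900002", base_count=12, distractor="absent"),
    ]
    return SimulationConfig(
        seed=seed,
        species=species,
        go_terms=terms,
        n_og_qualifying=6,
        n_og_present_only=5,
        n_og_minor=4,
        og_presence_quorum=5,
        og_expressed_quorum=4,
        n_responsive_og=1,
        n_plants=3,
    )


# ---------------------------------------------------------------------------
# plan: memberships, effects, thermal truth (shared by the generator ops)
# ---------------------------------------------------------------------------


class _Plan:
    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        seed = cfg.seed
        species = cfg.species
        sp_ids = [s.species_id for s in species]
        self.biome = {s.species_id: s.biome for s in species}

        # library design
        self.libraries: list[LibraryRecord] = []
        for s in species:
            for tr, n in (("control", s.n_control), ("cold", s.n_cold), ("hot", s.n_hot)):
                for i in range(n):
                    self.libraries.append(
                        LibraryRecord(
                            f"{s.species_id}_{tr}{i + 1}", s.species_id, tr, s.biome
                        )
                    )

        # GO member counts per term x species (distractor patterns included)
        qualifying = [t for t in cfg.go_terms if t.distractor is None]
        self.term_counts: dict[str, dict[str, int]] = {}
        for t in cfg.go_terms:
            rng = substream_rng(seed, "counts", t.term)
            counts = {}
            for j, s in enumerate(species):
                c = t.base_count + int(rng.integers(0, t.count_jitter + 1))
                if t.distractor == "low_count" and j == 0:
                    c = 9
                if t.distractor == "absent" and j == 0:
                    c = 0
                counts[s.species_id] = c
            self.term_counts[t.term] = counts

        # per-species effect realisations
        self.term_beta: dict[str, dict[str, tuple[float, float]]] = {}
        for t in cfg.go_terms:
            rng = substream_rng(seed, "beta", t.term)
            per_sp = {}
            for s in species:
                bh = t.beta_hot[s.biome] if isinstance(t.beta_hot, dict) else t.beta_hot
                bc = t.beta_cold[s.biome] if isinstance(t.beta_cold, dict) else t.beta_cold
                if t.species_jitter_sd > 0:
                    jit = rng.normal(0, t.species_jitter_sd, size=2)
                    if bh != 0:
                        bh += jit[0]
                    if bc != 0:
                        bc += jit[1]
                per_sp[s.species_id] = (float(bh), float(bc))
            self.term_beta[t.term] = per_sp

        # orthogroup structure
        rng = substream_rng(seed, "og_structure")
        n_sp = len(species)
        pq, eq = cfg.og_presence_quorum, cfg.og_expressed_quorum
        if pq > n_sp:
            raise ConfigError("og_presence_quorum exceeds species count")
        self.og_structure: dict[str, dict] = {}
        og_i = 0

        def new_og(n_present, n_expressed):
            nonlocal og_i
            og_i += 1
            og = f"OG{og_i:07d}"
            present = sorted(rng.choice(sp_ids, size=n_present, replace=False).tolist())
            expressed = sorted(rng.choice(present, size=n_expressed, replace=False).tolist())
            k = {sp: int(rng.integers(1, 4)) for sp in present}
            self.og_structure[og] = {
                "present": present, "expressed": expressed, "k": k, "beta_hot": 0.0,
            }
            return og

        self.responsive_ogs: dict[str, float] = {}
        for j in range(cfg.n_og_qualifying):
            npres = int(rng.integers(pq, n_sp + 1))
            nexpr = int(rng.integers(eq, npres + 1))
            og = new_og(npres, nexpr)
            if j < cfg.n_responsive_og:
                beta = cfg.og_beta_hot - 0.2 * j
                self.og_structure[og]["beta_hot"] = beta
                self.responsive_ogs[og] = beta
        for _ in range(cfg.n_og_present_only):
            npres = int(rng.integers(pq, n_sp + 1))
            nexpr = int(rng.integers(0, eq))
            new_og(npres, nexpr)
        for _ in range(cfg.n_og_minor):
            npres = int(rng.integers(1, pq))
            nexpr = int(rng.integers(0, npres + 1))
            new_og(npres, nexpr)

        # per-species gene allocation: exclusive blocks for responsive sets,
        # remainder shared by null terms and non-responsive orthogroups
        self.members: dict[str, dict[str, np.ndarray]] = {}  # term -> sp -> idx
        self.og_members: dict[str, dict[str, list[int]]] = {}
        self.og_low_members: dict[str, dict[str, list[int]]] = {}
        self.gene_beta: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        responsive_terms = [t for t in cfg.go_terms if t.responsive()]
        other_terms = [t for t in cfg.go_terms if not t.responsive()]
        for s in species:
            sp = s.species_id
            rng_s = substream_rng(seed, "alloc", sp)
            perm = rng_s.permutation(s.n_expressed)
            ptr = 0
            bhot = np.zeros(s.n_expressed + s.n_low)
            bcold = np.zeros(s.n_expressed + s.n_low)
            for t in responsive_terms:
                c = self.term_counts[t.term][sp]
                idx = perm[ptr: ptr + c]
                ptr += c
                self.members.setdefault(t.term, {})[sp] = np.sort(idx)
                bh, bc = self.term_beta[t.term][sp]
                bhot[idx] = bh
                bcold[idx] = bc
            for og, struct in self.og_structure.items():
                if struct["beta_hot"] != 0 and sp in struct["expressed"]:
                    k = struct["k"][sp]
                    idx = perm[ptr: ptr + k]
                    ptr += k
                    self.og_members.setdefault(og, {})[sp] = sorted(int(i) for i in idx)
                    bhot[idx] = struct["beta_hot"]
            if ptr > s.n_expressed:
                raise ConfigError(
                    f"{sp}: responsive gene demand {ptr} exceeds {s.n_expressed} genes"
                )
            remainder = perm[ptr:]
            for t in other_terms:
                c = self.term_counts[t.term][sp]
                if c == 0:
                    continue
                if c > remainder.size:
                    raise ConfigError(f"{sp}: not enough genes for {t.term}")
                idx = rng_s.choice(remainder, size=c, replace=False)
                self.members.setdefault(t.term, {})[sp] = np.sort(idx)
            for og, struct in self.og_structure.items():
                if struct["beta_hot"] != 0:
                    if sp in struct["present"] and sp not in struct["expressed"]:
                        k = struct["k"][sp]
                        low = rng_s.choice(s.n_low, size=k, replace=False)
                        self.og_low_members.setdefault(og, {})[sp] = sorted(
                            s.n_expressed + int(i) for i in low
                        )
                    continue
                if sp in struct["expressed"]:
                    k = struct["k"][sp]
                    idx = rng_s.choice(remainder, size=k, replace=False)
                    self.og_members.setdefault(og, {})[sp] = sorted(int(i) for i in idx)
                elif sp in struct["present"]:
                    k = struct["k"][sp]
                    low = rng_s.choice(s.n_low, size=k, replace=False)
                    self.og_low_members.setdefault(og, {})[sp] = sorted(
                        s.n_expressed + int(i) for i in low
                    )
            self.gene_beta[sp] = (bhot, bcold)

        # thermal truth
        th = cfg.thermal
        self.thermal_baselines: dict[str, dict[str, float]] = {}
        self.thermal_deltas: dict[str, dict[str, float]] = {}
        acclim_hot = {
            sp: self.term_beta[_ACCLIM_HOT_TERM][sp][0]
            for sp in sp_ids
        } if _ACCLIM_HOT_TERM in self.term_beta else {sp: 0.7 for sp in sp_ids}
        acclim_cold = {
            sp: self.term_beta[_ACCLIM_COLD_TERM][sp][1]
            for sp in sp_ids
        } if _ACCLIM_COLD_TERM in self.term_beta else {sp: -0.5 for sp in sp_ids}
        self.acclim_hot, self.acclim_cold = acclim_hot, acclim_cold
        mean_bh = float(np.mean(list(acclim_hot.values())))
        mean_bc = float(np.mean(list(acclim_cold.values())))
        for sp in sp_ids:
            rng_t = substream_rng(seed, "thermal", sp)
            tcrit_hot = th.tcrit_hot_mean + rng_t.normal(0, th.tcrit_hot_sd)
            tmax_hot = tcrit_hot + th.tmax_hot_offset + rng_t.normal(0, 1.0)
            tcrit_cold = th.tcrit_cold_mean + rng_t.normal(0, th.tcrit_cold_sd)
            tmax_cold = tcrit_cold + th.tmax_cold_offset + rng_t.normal(0, 1.0)
            self.thermal_baselines[sp] = {
                "tcrit_hot": tcrit_hot, "tmax_hot": tmax_hot,
                "tcrit_cold": tcrit_cold, "tmax_cold": tmax_cold,
            }
            d_hot = (
                th.delta_hot_intercept
                + th.delta_hot_slope * (acclim_hot[sp] - mean_bh)
                + rng_t.normal(0, th.delta_hot_noise_sd)
            )
            d_cold = (
                th.delta_cold_intercept
                + th.delta_cold_slope * (acclim_cold[sp] - mean_bc)
                + rng_t.normal(0, th.delta_cold_noise_sd)
            )
            self.thermal_deltas[sp] = {
                "Tcrit_hot": d_hot,
                "Tmax_hot": 0.6 * d_hot + rng_t.normal(0, 0.2),
                "Tcrit_cold": d_cold,
                "Tmax_cold": 0.6 * d_cold + rng_t.normal(0, 0.2),
            }

    def gene_ids(self, s: SpeciesDesign) -> list[str]:
        return [f"{s.species_id}_g{i:05d}" for i in range(s.n_expressed + s.n_low)]


def _ground_truth(plan: _Plan) -> GroundTruth:
    cfg = plan.cfg
    qualifying = sorted(t.term for t in cfg.go_terms if t.distractor is None)
    sizes = {
        term: subset_size(plan.term_counts[term].values())
        for term in qualifying
    }
    effects = {}
    for t in cfg.go_terms:
        if t.distractor is not None:
            continue
        effects[t.term] = {
            "beta_hot": t.beta_hot, "beta_cold": t.beta_cold,
            "per_species": {
                sp: list(v) for sp, v in plan.term_beta[t.term].items()
            },
        }
    s2 = cfg.sigma_species ** 2
    l2 = cfg.sigma_library ** 2
    return GroundTruth(
        retained_per_species={s.species_id: s.n_expressed for s in cfg.species},
        qualifying_terms=qualifying,
        subset_sizes=sizes,
        term_effects=effects,
        true_icc=s2 / (s2 + l2),
        sigma_species=cfg.sigma_species,
        sigma_library=cfg.sigma_library,
        n_og_present_quorum=cfg.n_og_qualifying + cfg.n_og_present_only,
        n_og_expressed_quorum=cfg.n_og_qualifying,
        og_quorums=(cfg.og_presence_quorum, cfg.og_expressed_quorum),
        responsive_ogs=dict(plan.responsive_ogs),
        species_beta_hot_acclim=dict(plan.acclim_hot),
        species_beta_cold_acclim=dict(plan.acclim_cold),
        thermal_baselines=plan.thermal_baselines,
        thermal_deltas=plan.thermal_deltas,
    )


# ---------------------------------------------------------------------------
# generator operations
# ---------------------------------------------------------------------------


def generate_expression(
    config: SimulationConfig, plan: _Plan | None = None
) -> tuple[dict[str, SpeciesExpression], list[LibraryRecord], GroundTruth]:
    """Simulate TPM matrices for every species plus metadata and truth."""
    plan = plan or _Plan(config)
    cfg = config
    seed = cfg.seed
    expr: dict[str, SpeciesExpression] = {}
    for s in cfg.species:
        sp = s.species_id
        rng = substream_rng(seed, "expr", sp)
        n_genes = s.n_expressed + s.n_low
        libs = [l for l in plan.libraries if l.species_id == sp]
        n_libs = len(libs)
        mu = np.empty(n_genes)
        mu[: s.n_expressed] = np.clip(
            rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, s.n_expressed),
            4.5, None,
        )
        mu[s.n_expressed:] = np.clip(
            rng.normal(cfg.low_log2_mean, cfg.low_log2_sd, s.n_low), None, 2.0
        )
        u_s = rng.normal(0, cfg.sigma_species)
        v = rng.normal(0, cfg.sigma_library, n_libs)
        eps = rng.normal(0, cfg.sigma_gene, (n_genes, n_libs))
        is_hot = np.array([l.treatment == "hot" for l in libs], dtype=float)
        is_cold = np.array([l.treatment == "cold" for l in libs], dtype=float)
        bhot, bcold = plan.gene_beta[sp]
        x = (
            mu[:, None]
            + u_s
            + v[None, :]
            + bhot[:, None] * is_hot[None, :]
            + bcold[:, None] * is_cold[None, :]
            + eps
        )
        tpm = np.exp2(x)
        # deterministic filter-margin rescue: keeps planted retained counts
        # exact; row scaling does not change fold changes or z-scores
        thr = cfg.tpm_threshold
        means = tpm.mean(axis=1)
        hi = np.arange(s.n_expressed)
        lo = np.arange(s.n_expressed, n_genes)
        bad_hi = hi[means[hi] < 1.2 * thr]
        tpm[bad_hi] *= (2.0 * thr / means[bad_hi])[:, None]
        bad_lo = lo[means[lo] > 0.8 * thr]
        tpm[bad_lo] *= (0.5 * thr / means[bad_lo])[:, None]
        frame = pd.DataFrame(
            tpm, index=pd.Index(plan.gene_ids(s), name="gene_id"),
            columns=[l.library_id for l in libs],
        )
        expr[sp] = SpeciesExpression(sp, frame)
    return expr, list(plan.libraries), _ground_truth(plan)


def generate_annotations(
    config: SimulationConfig, plan: _Plan | None = None
) -> tuple[dict[str, AnnotationTable], dict[str, dict[str, list[str]]]]:
    """Planted GO annotations and orthogroup table, with distractors."""
    plan = plan or _Plan(config)
    annotations: dict[str, AnnotationTable] = {}
    for s in config.species:
        sp = s.species_id
        ids = plan.gene_ids(s)
        go: dict[str, set[str]] = {}
        for term, per_sp in plan.members.items():
            for idx in per_sp.get(sp, []):
                go.setdefault(ids[idx], set()).add(term)
        # annotate a handful of below-filter genes too: they must be
        # excluded downstream by the expression filter, not the parser
        rng = substream_rng(config.seed, "low_annot", sp)
        some_terms = sorted(plan.members)[:3]
        for idx in rng.choice(s.n_low, size=min(20, s.n_low), replace=False):
            go.setdefault(ids[s.n_expressed + int(idx)], set()).add(some_terms[int(idx) % len(some_terms)])
        annotations[sp] = AnnotationTable(species_id=sp, go=go)

    orthogroups: dict[str, dict[str, list[str]]] = {}
    id_map = {s.species_id: plan.gene_ids(s) for s in config.species}
    for og in sorted(plan.og_structure):
        members: dict[str, list[str]] = {}
        for sp, idxs in plan.og_members.get(og, {}).items():
            members[sp] = [id_map[sp][i] for i in idxs]
        for sp, idxs in plan.og_low_members.get(og, {}).items():
            members.setdefault(sp, []).extend(id_map[sp][i] for i in idxs)
        orthogroups[og] = members
    return annotations, orthogroups


def _trace_f0(x, psi, x_peak, base=0.2, slow=0.001, fast=0.05, fall=0.08):
    rise = fast * np.clip(np.minimum(x, x_peak) - psi, 0, None)
    decay = fall * np.clip(x - x_peak, 0, None)
    return base + slow * (x - x[0]) + rise - decay


def generate_traces(
    config: SimulationConfig, plan: _Plan | None = None
) -> list[FluorescenceTrace]:
    """Two-segment (plus peak-decay) F0 ramps with known breakpoints."""
    plan = plan or _Plan(config)
    th = config.thermal
    step_heat = th.heating_rate / 3600.0 * th.log_interval_s
    step_cool = th.cooling_rate / 3600.0 * th.log_interval_s
    t_heat = np.arange(20.0, 65.0 + 1e-9, step_heat)
    t_cool = np.arange(20.0, -25.0 - 1e-9, -step_cool)
    traces: list[FluorescenceTrace] = []
    for s in config.species:
        sp = s.species_id
        base = plan.thermal_baselines[sp]
        delta = plan.thermal_deltas[sp]
        rng = substream_rng(config.seed, "traces", sp)
        for treatment in ("control", "cold", "hot"):
            for rep in range(config.n_plants):
                tc_hot = base["tcrit_hot"] + (delta["Tcrit_hot"] if treatment == "hot" else 0.0)
                tm_hot = base["tmax_hot"] + (delta["Tmax_hot"] if treatment == "hot" else 0.0)
                tc_cold = base["tcrit_cold"] + (delta["Tcrit_cold"] if treatment == "cold" else 0.0)
                tm_cold = base["tmax_cold"] + (delta["Tmax_cold"] if treatment == "cold" else 0.0)
                jit = rng.normal(0, th.plant_jitter_sd, 4)
                f_heat = _trace_f0(t_heat, tc_hot + jit[0], tm_hot + jit[1])
                f_heat = f_heat + rng.normal(0, config.trace_noise_sd, t_heat.size)
                traces.append(
                    FluorescenceTrace(
                        sample_id=f"{sp}_{treatment}{rep + 1}_heat",
                        species_id=sp, treatment=treatment, direction="heating",
                        temperature=t_heat.copy(), f0=np.clip(f_heat, 0, None),
                    )
                )
                x = -t_cool  # cooling analysed on the negated axis
                f_cool = _trace_f0(x, -(tc_cold + jit[2]), -(tm_cold + jit[3]))
                f_cool = f_cool + rng.normal(0, config.trace_noise_sd, t_cool.size)
                traces.append(
                    FluorescenceTrace(
                        sample_id=f"{sp}_{treatment}{rep + 1}_cool",
                        species_id=sp, treatment=treatment, direction="cooling",
                        temperature=t_cool.copy(), f0=np.clip(f_cool, 0, None),
                    )
                )
    return traces


def simulate_dataset(config: SimulationConfig) -> SimBundle:
    """Generate the full study bundle (expression, annotations, traces, truth)."""
    plan = _Plan(config)
    expr, metadata, truth = generate_expression(config, plan)
    annotations, orthogroups = generate_annotations(config, plan)
    traces = generate_traces(config, plan)
    return SimBundle(
        config=config, metadata=metadata, expression=expr,
        annotations=annotations, orthogroups=orthogroups,
        traces=traces, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers: emit every input format the pipeline consumes
# ---------------------------------------------------------------------------

_CC_DECOY = "GO:0005737^cellular_component^cytoplasm"


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    """Write the bundle in the on-disk dialects the io layer reads back."""
    out = Path(out_dir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)

    meta = pd.DataFrame(
        [(r.library_id, r.species_id, r.treatment, r.biome) for r in bundle.metadata],
        columns=["library_id", "species_id", "treatment", "biome"],
    )
    meta.to_csv(out / "metadata.csv", index=False, lineterminator="\n")

    for sp, expr in sorted(bundle.expression.items()):
        write_generic_tpm(expr, out / "expression" / f"{sp}.tsv")

    for sp, ann in sorted(bundle.annotations.items()):
        rows = []
        for gene in sorted(ann.go):
            terms = sorted(ann.go[gene])
            cell = "`".join(
                f"{t}^biological_process^synthetic process {t[-3:]}" for t in terms
            )
            rows.append(
                {
                    "#gene_id": gene,
                    "transcript_id": f"{gene}_i1",
                    "gene_ontology_BLASTX": f"{cell}`{_CC_DECOY}",
                    "gene_ontology_Pfam": cell if len(terms) > 1 else ".",
                }
            )
        pd.DataFrame(rows).to_csv(
            out / "annotations" / f"{sp}_trinotate.tsv", sep="\t", index=False,
            lineterminator="\n",
        )

    species_ids = sorted(bundle.expression)
    og_rows = []
    for og in sorted(bundle.orthogroups):
        row = {"Orthogroup": og}
        for sp in species_ids:
            row[sp] = ", ".join(bundle.orthogroups[og].get(sp, []))
        og_rows.append(row)
    pd.DataFrame(og_rows).to_csv(
        out / "Orthogroups.tsv", sep="\t", index=False, lineterminator="\n"
    )

    trace_frames = []
    for tr in bundle.traces:
        trace_frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "species_id": tr.species_id,
                    "treatment": tr.treatment,
                    "direction": tr.direction,
                    "temperature_C": tr.temperature,
                    "f0": tr.f0,
                }
            )
        )
    pd.concat(trace_frames, ignore_index=True).to_csv(
        out / "traces.csv", index=False, lineterminator="\n"
    )

    with open(out / "ground_truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())
        fh.write("\n")
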