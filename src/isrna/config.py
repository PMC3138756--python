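"""Configuration objects for the synthetic-data generator and the pipeline.

``SimConfig`` describes the simulated study: the annotation universe, the
clone library, the conservation tracks and the loop-design microarray.  Its
defaults encode the study conditions the downstream analysis was built for:
82 novel loci partitioned 27/44/11 across intergenic, sense-intronic and
antisense-intronic contexts, 218 known is-ncRNA loci, a clone-count law
under which most novel loci are single-clone, an 18-species conservation
panel, and planted >2-fold expression effects on a minority of transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: 18-species conservation panel (human first), mirroring a vertebrate
#: alignment restricted to well-covered genomes.
DEFAULT_SPECIES: Tuple[str, ...] = (
    "human", "chimp", "rhesus",
    "mouse", "rat",
    "dog", "cat", "horse", "cow", "rabbit", "elephant",
    "chicken", "lizard", "frog", "zebrafish", "fugu", "medaka", "stickleback",
)

#: Clade labels used by the conservation-group rules.
DEFAULT_CLADES: Dict[str, str] = {
    "human": "primate", "chimp": "primate", "rhesus": "primate",
    "mouse": "rodent", "rat": "rodent",
    "dog": "other_eutherian", "cat": "other_eutherian",
    "horse": "other_eutherian", "cow": "other_eutherian",
    "rabbit": "other_eutherian", "elephant": "other_eutherian",
    "chicken": "non_mammal", "lizard": "non_mammal", "frog": "non_mammal",
    "zebrafish": "non_mammal", "fugu": "non_mammal",
    "medaka": "non_mammal", "stickleback": "non_mammal",
}

#: Non-human primate genomes used for the presence/absence matrix, with the
#: substitution divergence applied when an ortholog is present.
DEFAULT_PRIMATE_DIVERGENCE: Dict[str, float] = {
    "chimp": 0.02,
    "orangutan": 0.04,
    "rhesus": 0.07,
    "marmoset": 0.12,
}


def largest_remainder(proportions: List[float], total: int) -> List[int]:
    """Apportion ``total`` into integer counts matching ``proportions``.

    Uses the largest-remainder (Hamilton) method so exact rational mixes
    (e.g. 27/82, 44/82, 11/82 over 82) reproduce their numerators exactly.
    """
    if total < 0:
        raise ConfigError("total must be non-negative")
    s = sum(proportions)
    if abs(s - 1.0) > 1e-9:
        raise ConfigError(f"proportions sum to {s!r}, expected 1 within 1e-9")
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class SimConfig:
    """Parameters of one simulated study.  ``seed`` determines all outputs."""

    seed: int = 1

    # --- genome & annotation -------------------------------------------
    genome_length: int = 2_400_000
    n_chromosomes: int = 4
    n_genes: int = 400
    exons_per_gene: int = 3
    n_known_ncrna: Dict[str, int] = field(default_factory=lambda: {
        "rRNA": 10, "tRNA": 10, "snoRNA": 100, "snRNA": 60, "misc": 58,
    })
    n_novel: int = 82
    novel_context_mix: Dict[str, float] = field(default_factory=lambda: {
        "intergenic": 27 / 82,
        "sense_intronic": 44 / 82,
        "antisense_intronic": 11 / 82,
    })

    # --- clone library --------------------------------------------------
    insert_length_range: Tuple[int, int] = (50, 500)
    #: zero-truncated geometric success parameter for novel-locus clone
    #: counts (p = 0.7 makes ~70% of novel loci single-clone)
    clone_count_p: float = 0.7
    #: same law for known loci, with a smaller p so known is-ncRNAs appear
    #: as multi-clone, higher-expression species
    clone_count_p_known: float = 0.12
    #: fraction of all reads drawn from mRNA exons / rRNA / tRNA loci
    decoy_fraction: float = 0.14
    adapter_5: str = "ATCGTAGGCACCTGAAATCG"
    adapter_3: str = "TGGAATTCTCGGGTGCCAAG"

    # --- conservation ----------------------------------------------------
    species_list: Tuple[str, ...] = DEFAULT_SPECIES
    clades: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLADES))
    conservation_group_mix: Dict[str, float] = field(default_factory=lambda: {
        "eutherian": 31 / 82,
        "non_rodent_mammal": 22 / 82,
        "primate_only": 14 / 82,
        "beyond_eutherian": 5 / 82,
        "other": 10 / 82,
    })
    #: per-base Gaussian noise of the simulated conservation tracks
    track_noise_sd: float = 0.1

    # --- snoRNA motif planting ------------------------------------------
    n_sno_cd: int = 4
    n_sno_haca: int = 9
    n_sno_scarna: int = 1

    # --- loop-design microarray ------------------------------------------
    tissues: Tuple[str, ...] = ("brain", "heart", "liver", "lung", "spleen")
    stages: Tuple[str, ...] = ("13w", "14w", "20w", "24w")
    #: fraction of novel transcripts with a planted >2-fold tissue effect
    effect_fraction: float = 34 / 82
    effect_fraction_known: float = 46 / 244
    stage_effect_fraction: float = 7 / 82
    stage_effect_fraction_known: float = 1 / 244
    effect_size_log2: float = 1.5
    noise_sd_log2: float = 0.3
    dye_offset_sd: float = 0.2
    n_replicates: int = 3

    # --- gene sets --------------------------------------------------------
    enriched_set_size: int = 6
    enriched_hosts: int = 4
    n_decoy_sets: int = 19

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        lo, hi = self.insert_length_range
        if not (1 <= lo <= hi <= self.genome_length):
            raise ConfigError(
                "insert_length_range must satisfy 1 <= min <= max <= genome_length"
            )
        for name, mix in (
            ("novel_context_mix", self.novel_context_mix),
            ("conservation_group_mix", self.conservation_group_mix),
        ):
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {s!r}, expected 1 within 1e-9")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} has negative proportions")
        if not (0 < self.clone_count_p <= 1 and 0 < self.clone_count_p_known <= 1):
            raise ConfigError("clone-count parameters must lie in (0, 1]")
        if not (0 <= self.decoy_fraction < 1):
            raise ConfigError("decoy_fraction must lie in [0, 1)")
        if not self.adapter_5 or not self.adapter_3:
            raise ConfigError("adapters must be non-empty")
        if not self.species_list or self.species_list[0] != "human":
            raise ConfigError("species_list must be non-empty with human first")
        missing = [s for s in self.species_list if s not in self.clades]
        if missing:
            raise ConfigError(f"species without clade label: {missing}")
        if self.effect_size_log2 < 1:
            raise ConfigError("effect_size_log2 must be >= 1 (a >2-fold effect)")
        for name in ("noise_sd_log2", "dye_offset_sd", "track_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.tissues) < 2 or len(self.stages) < 2:
            raise ConfigError("at least two tissue and two stage samples required")
        n_sno = self.n_sno_cd + self.n_sno_haca + self.n_sno_scarna
        if n_sno > self.n_novel:
            raise ConfigError("more snoRNA motif plants than novel loci")

    # ------------------------------------------------------------------
    def novel_context_counts(self) -> Dict[str, int]:
        keys = list(self.novel_context_mix)
        counts = largest_remainder([self.novel_context_mix[k] for k in keys], self.n_novel)
        return dict(zip(keys, counts))

    def conservation_group_counts(self) -> Dict[str, int]:
        keys = list(self.conservation_group_mix)
        counts = largest_remainder(
            [self.conservation_group_mix[k] for k in keys], self.n_novel
        )
        return dict(zip(keys, counts))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species_list"] = list(self.species_list)
        d["tissues"] = list(self.tissues)
        d["stages"] = list(self.stages)
        d["insert_length_range"] = list(self.insert_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("species_list", "tissues", "stages", "insert_length_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
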