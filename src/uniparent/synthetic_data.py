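"""Forward-in-time haploid simulator for uniparental markers.

The generator emulates the demographic structure the downstream analyses
assume for a founder population such as the European Roma:

* a source gene pool containing several divergent founder lineages,
* a founder bottleneck ``G`` generations ago (default 50),
* continuous per-generation replacement of lineages by an external
  (host) gene pool at a marker-specific rate ``m`` — the "constant gene
  flow" model, under which the expected surviving founder-lineage
  fraction after ``G`` generations is ``(1 - m) ** G``,
* fission of the population into labelled migrant groups that then drift
  independently at constant size (optionally growing exponentially, which
  produces star-like haplotype networks),
* finite-sites mutation: each transmitted lineage acquires
  ``Poisson(mu * L)`` substitutions at uniformly chosen sites, so
  back-mutation is possible, exactly as in the finite alignments the
  estimators consume.

Two markers differ only in their length and per-site rate: mtDNA-like
(16,569 sites) and MSY-like (100,000 sites standing in for the ~9 Mb
callable region, with the clock scaled accordingly).  The external donor
pool is fixed at simulation start; lineages it donates carry an origin
label (e.g. ``external:European``) recorded in the ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sequence_io import HaploidAlignment, SampleTable

_ALPHABET = np.array(list("ACGT"))

#: Assumed generation time in years, used to convert per-year clock rates
#: into per-generation mutation rates.
GENERATION_YEARS = 29.0
#: mtDNA coding-region substitution rate, per site per year.
MT_RATE_PER_YEAR = 1.708e-8
#: Fast MSY substitution rate, per site per year.
MSY_RATE_PER_YEAR = 1e-9


def default_mu(marker: str) -> float:
    """Per-site per-generation mutation rate implied by the marker clock."""
    rate = MT_RATE_PER_YEAR if marker == "mtDNA" else MSY_RATE_PER_YEAR
    return rate * GENERATION_YEARS


@dataclass
class FissionEvent:
    """At ``generation``, split the population into named groups of given sizes.

    Sizes must sum to the current population size; each group then evolves
    as an independent Wright-Fisher population of constant size.
    """

    generation: int
    sizes: dict[str, int]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated marker scenario."""

    marker: str = "mtDNA"
    length: int = 16_569
    mu: float | None = None          # per site per generation; None -> marker clock
    generations: int = 50
    founder_size: int = 500
    m: float = 0.0                   # per-generation external replacement rate
    n_founder_lineages: int = 4
    founder_divergence: int = 25     # pairwise-ish mutations between founder lineages
    external_origins: tuple[str, ...] = ("European", "West Asian")
    external_divergence: int = 40    # mutations separating donor lineages from root
    fissions: tuple[FissionEvent, ...] = ()
    growth_rate: float = 0.0         # per-generation exponential growth after founding
    sample_size: int | None = None   # individuals sampled from the final generation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m < 1):
            raise ConfigError(f"replacement rate m={self.m} must be in [0, 1)")
        if self.generations < 1 or self.length < 1 or self.founder_size < 1:
            raise ConfigError("generations, length and founder_size must be >= 1")
        if self.n_founder_lineages < 1:
            raise ConfigError("need at least one founder lineage")
        if self.mu is None:
            self.mu = default_mu(self.marker)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fissions = tuple(
            FissionEvent(int(f["generation"]), {str(k): int(v) for k, v in f["sizes"].items()})
            for f in raw.pop("fissions", [])
        )
        return cls(fissions=fissions, **raw)


@dataclass
class SimTruth:
    """Ground truth of a simulated scenario, for parameter-recovery tests."""

    origins: list[str]               # per final sample: "founder" or "external:<origin>"
    m: float
    generations: int
    marker: str
    founder_lineage: list[int]       # founder-lineage index at t0 ancestry (-1 if external)
    seed: int

    @property
    def founder_fraction(self) -> float:
        return sum(o == "founder" for o in self.origins) / len(self.origins)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def expected_founder_fraction(m: float, generations: int) -> float:
    """Expected surviving founder-lineage fraction under constant replacement.

    Each lineage independently survives a generation with probability
    ``1 - m``, so after ``G`` generations the expectation is ``(1-m)**G``.
    """
    if not (0 <= m < 1):
        raise ConfigError(f"m={m} must be in [0, 1)")
    if generations < 0:
        raise ConfigError("generations must be >= 0")
    return (1.0 - m) ** generations


def _divergent_haplotypes(root: np.ndarray, n: int, n_mut: int,
                          rng: np.random.Generator) -> np.ndarray:
    """``n`` copies of ``root`` each carrying ``n_mut`` private substitutions."""
    haps = np.tile(root, (n, 1))
    L = root.size
    for i in range(n):
        sites = rng.choice(L, size=min(n_mut, L), replace=False)
        haps[i, sites] = (haps[i, sites] + rng.integers(1, 4, size=sites.size)) % 4
    return haps


def simulate(cfg: ScenarioConfig) -> tuple[HaploidAlignment, SampleTable, SimTruth]:
    """Run the forward Wright-Fisher scenario and return alignment + metadata
    + ground truth.

    Per generation each individual copies a uniformly chosen parent from its
    own group, is replaced by a random external-pool haplotype with
    probability ``m`` (its origin switching to that donor's label), and then
    acquires ``Poisson(mu*L)`` substitutions at uniform sites.  Seeded runs
    are bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    L, N = cfg.length, cfg.founder_size

    fissions = sorted(cfg.fissions, key=lambda f: f.generation)
    for f in fissions:
        if not (1 <= f.generation <= cfg.generations):
            raise ConfigError(f"fission at generation {f.generation} outside 1..{cfg.generations}")

    root = rng.integers(0, 4, size=L, dtype=np.int8)
    founder_haps = _divergent_haplotypes(root, cfg.n_founder_lineages,
                                         cfg.founder_divergence, rng)
    pool_haps = _divergent_haplotypes(root, len(cfg.external_origins),
                                      cfg.external_divergence, rng)

    # initial bottleneck population: founder lineages round-robin
    lineage = np.arange(N) % cfg.n_founder_lineages
    seqs = founder_haps[lineage].copy()
    origin = np.zeros(N, dtype=np.int64)  # 0 = founder, 1+i = external origin i
    groups = np.zeros(N, dtype=np.int64)
    group_names = ["founder"]

    fission_at = {f.generation: f for f in fissions}

    for gen in range(1, cfg.generations + 1):
        if gen in fission_at:
            ev = fission_at[gen]
            if sum(ev.sizes.values()) != len(seqs):
                raise ConfigError(
                    f"fission sizes {ev.sizes} do not sum to population size {len(seqs)}"
                )
            perm = rng.permutation(len(seqs))
            groups = np.empty(len(seqs), dtype=np.int64)
            group_names = list(ev.sizes)
            start = 0
            for gi, (name, size) in enumerate(ev.sizes.items()):
                groups[perm[start:start + size]] = gi
                start += size

        # Wright-Fisher update within each group (with optional growth)
        new_index: list[np.ndarray] = []
        new_groups: list[np.ndarray] = []
        for gi in range(len(group_names)):
            members = np.where(groups == gi)[0]
            size = members.size
            if cfg.growth_rate > 0:
                size = max(1, int(round(size * (1.0 + cfg.growth_rate))))
            parents = members[rng.integers(0, members.size, size=size)]
            new_index.append(parents)
            new_groups.append(np.full(size, gi, dtype=np.int64))
        parents = np.concatenate(new_index)
        groups = np.concatenate(new_groups)
        seqs = seqs[parents]
        lineage = lineage[parents]
        origin = origin[parents]

        # external replacement
        if cfg.m > 0:
            replaced = np.where(rng.random(len(seqs)) < cfg.m)[0]
            if replaced.size:
                donors = rng.integers(0, len(cfg.external_origins), size=replaced.size)
                seqs[replaced] = pool_haps[donors]
                origin[replaced] = donors + 1
                lineage[replaced] = -1

        # finite-sites mutation
        n_mut = rng.poisson(cfg.mu * L, size=len(seqs))
        hit = np.where(n_mut > 0)[0]
        for i in hit:
            sites = rng.integers(0, L, size=n_mut[i])
            seqs[i, sites] = (seqs[i, sites] + rng.integers(1, 4, size=n_mut[i])) % 4

    if cfg.sample_size is not None:
        if cfg.sample_size > len(seqs):
            raise ConfigError(
                f"sample_size {cfg.sample_size} exceeds final population {len(seqs)}"
            )
        take = np.sort(rng.choice(len(seqs), size=cfg.sample_size, replace=False))
        seqs, origin, lineage, groups = (
            seqs[take], origin[take], lineage[take], groups[take]
        )

    n_final = len(seqs)
    width = max(4, len(str(n_final)))
    sample_ids = [f"{cfg.marker[:2].upper()}{i:0{width}d}" for i in range(n_final)]
    matrix = _ALPHABET[seqs]
    aln = HaploidAlignment(sample_ids, np.arange(1, L + 1), matrix, cfg.marker)

    labels = [group_names[g] for g in groups]
    country = [lab.split(":")[0] for lab in labels]
    route = [lab.split(":")[1] if ":" in lab else lab for lab in labels]
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "marker": cfg.marker,
                "country": country,
                "route": route,
                "individual_id": [None] * n_final,
            }
        )
    )
    origin_labels = ["founder"] + [f"external:{o}" for o in cfg.external_origins]
    truth = SimTruth(
        origins=[origin_labels[o] for o in origin],
        m=cfg.m,
        generations=cfg.generations,
        marker=cfg.marker,
        founder_lineage=lineage.tolist(),
        seed=cfg.seed,
    )
    return aln, table, truth


def roma_like_fissions(founder_size: int, generation: int = 25) -> tuple[FissionEvent, ...]:
    """A convenience fission schedule mimicking country-by-route migrant groups."""
    names = [
        "Macedonia:Balkan", "Romania:Vlax", "Hungary:Vlax", "Hungary:Romungro",
        "Ukraine:Romungro", "Lithuania:North-Western", "Spain:North-Western",
    ]
    base, extra = divmod(founder_size, len(names))
    sizes = {n: base + (1 if i < extra else 0) for i, n in enumerate(names)}
    return (FissionEvent(generation, sizes),)
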