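"""Seeded generators for every input the analysis pipeline consumes.

The default configuration emulates the structure of the study system: five
populations of 18-41 diploids, per-population MHC allele pools of 2-29
alleles with near-zero overlap between populations, ~73-codon coding
alleles carrying a subset of positively selected residues (elevated
nonsynonymous acceptance) and an optional recombination breakpoint, nine
low-diversity microsatellite loci (2-5 alleles each), and genotype sampling
at Hardy-Weinberg equilibrium or with a heterozygote deficit (f_is > 0).

A single root seed spawns independent substreams per stage, so adding a
stage never perturbs the draws of an earlier one, and identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .differentiation import geographic_distance_matrix
from .model import (
    AlleleCatalog,
    DistanceMatrixLabeled,
    GenotypeRecord,
    PopulationGenotypes,
)
from .selection import AA, BASES, CODON_INDEX, CODONS

__all__ = [
    "SimulationConfig",
    "simulate_allele_pools",
    "simulate_genotypes",
    "simulate_microsatellites",
    "simulate_landscape",
    "simulate_dataset",
    "random_tree",
    "evolve_sequences",
    "simulate_two_tree_alignment",
]

# consensus positively selected residues of the DAB beta-1 fragment
DEFAULT_SELECTED_CODONS = frozenset({2, 11, 23, 32, 42, 52, 55, 59, 63, 71, 72})


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_populations: int = 5
    population_names: tuple[str, ...] = (
        "Brynderwyn",
        "NorthernCoromandel",
        "CentralCoromandel",
        "SouthernCoromandel",
        "Otawa",
    )
    diploids_per_population: tuple[int, ...] = (18, 41, 22, 21, 19)
    alleles_per_population: tuple[int, ...] = (14, 29, 21, 11, 2)
    pool_overlap: float = 0.04
    freq_concentration: float = 0.8
    f_is: float = 0.4
    n_codons: int = 73
    selected_codons: frozenset[int] = DEFAULT_SELECTED_CODONS
    selected_omega: float = 5.0
    neutral_omega: float = 0.5
    tree_scale: float = 0.03  # expected substitutions/site per tree-depth unit
    recombination_breakpoint: Optional[int] = 162
    recombinant_fraction: float = 0.15
    n_microsat_loci: int = 9
    microsat_alleles_range: tuple[int, int] = (2, 5)
    microsat_drift: float = 10.0  # Dirichlet concentration scale; lower = more drift
    spatial_decay: float = 0.0  # >0: stepwise drift along a linear landscape (IBD)
    locus_name: str = "DAB"
    coordinates: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pool_overlap <= 1.0:
            raise ValueError("pool_overlap must lie in [0, 1]")
        if not 0.0 <= self.f_is <= 1.0:
            raise ValueError("f_is must lie in [0, 1]")
        if len(self.diploids_per_population) != self.n_populations:
            raise ValueError("diploids_per_population length mismatch")
        if len(self.alleles_per_population) != self.n_populations:
            raise ValueError("alleles_per_population length mismatch")
        if any(n < 1 for n in self.diploids_per_population):
            raise ValueError("population sizes must be positive")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Trees and sequence evolution
# ---------------------------------------------------------------------------


def random_tree(n_leaves: int, rng: np.random.Generator) -> object:
    """Random binary genealogy: ((left, right, t_left, t_right) | leaf index).

    Built by successive random joins with exponential branch increments
    (a Yule-like process; adequacy is judged by downstream property tests).
    """
    nodes: list[object] = list(range(n_leaves))
    heights = [0.0] * n_leaves
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new_height = max(heights[i], heights[j]) + rng.exponential(1.0 / len(nodes))
        node = (nodes[i], nodes[j], new_height - heights[i], new_height - heights[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [node]
        heights = [h for k, h in enumerate(heights) if k not in (i, j)] + [new_height]
    return nodes[0]


def _mutate_neutral(seq: np.ndarray, t: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor mutation of an integer-coded nucleotide array."""
    out = seq.copy()
    p = 0.75 * (1.0 - math.exp(-4.0 * rate * t / 3.0))
    hits = rng.random(out.size) < p
    if hits.any():
        shifts = rng.integers(1, 4, size=int(hits.sum()))
        out[hits] = (out[hits] + shifts) % 4
    return out


def evolve_sequences(
    tree: object, root_seq: np.ndarray, rate: float, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Evolve a nucleotide array down a :func:`random_tree` genealogy."""
    out: dict[int, np.ndarray] = {}

    def walk(node: object, seq: np.ndarray) -> None:
        if isinstance(node, int):
            out[node] = seq
            return
        left, right, t_left, t_right = node
        walk(left, _mutate_neutral(seq, t_left, rate, rng))
        walk(right, _mutate_neutral(seq, t_right, rate, rng))

    walk(tree, root_seq)
    return out


def _random_coding_root(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    sense = [i for i in range(64) if AA[i] != "*"]
    codons = rng.choice(sense, size=n_codons)
    seq = np.empty(3 * n_codons, dtype=np.int8)
    for c, codon_idx in enumerate(codons):
        codon = CODONS[int(codon_idx)]
        for k in range(3):
            seq[3 * c + k] = "ACGT".index(codon[k])
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[i] for i in seq)


def _mutate_selected(
    seq: np.ndarray,
    t: float,
    rate: float,
    omega: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Propose substitutions at Poisson rate; accept by selection class.

    Proposal intensity at a codon with dN/dS target w is scaled by
    max(1, w); a synonymous proposal is then accepted with probability
    min(1, 1/w) and a nonsynonymous one with min(1, w).  The realized
    synonymous rate stays at the base rate for every w while the
    nonsynonymous rate is w times it, so positively selected codons carry
    genuinely elevated amino-acid change.  Proposals creating stop codons
    are rejected.
    """
    out = seq.copy()
    pos_weight = np.repeat(np.maximum(1.0, omega), 3)
    pos_weight /= pos_weight.sum()
    n_prop = rng.poisson(rate * t * out.size * float(np.mean(np.maximum(1.0, omega))))
    for _ in range(n_prop):
        pos = int(rng.choice(out.size, p=pos_weight))
        new_base = (out[pos] + int(rng.integers(1, 4))) % 4
        codon_i = pos // 3
        start = 3 * codon_i
        old_codon = _decode(out[start : start + 3])
        new = out.copy()
        new[pos] = new_base
        new_codon = _decode(new[start : start + 3])
        if _CODON_AA[new_codon] == "*":
            continue
        w = float(omega[codon_i])
        if _CODON_AA[new_codon] == _CODON_AA[old_codon]:
            accept = rng.random() < min(1.0, 1.0 / w) if w > 0 else True
        else:
            accept = rng.random() < min(1.0, w)
        if accept:
            out[pos] = new_base
    return out


_CODON_AA = {c: AA[CODON_INDEX[c]] for c in CODONS}


def _evolve_with_selection(
    tree: object,
    root_seq: np.ndarray,
    rate: float,
    omega: np.ndarray,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}

    def walk(node: object, seq: np.ndarray) -> None:
        if isinstance(node, int):
            out[node] = seq
            return
        left, right, t_left, t_right = node
        walk(left, _mutate_selected(seq, t_left, rate, omega, rng))
        walk(right, _mutate_selected(seq, t_right, rate, omega, rng))

    walk(tree, root_seq)
    return out


def simulate_two_tree_alignment(
    n_seqs: int,
    left_length: int,
    right_length: int,
    rng: np.random.Generator,
    rate: float = 0.15,
    discordant: bool = True,
) -> list[str]:
    """Nucleotide alignment whose two halves evolved on discordant trees.

    With ``discordant=False`` both segments share one tree (the
    no-recombination null).  Deep splits come from the exponential branch
    increments near the root of each random genealogy.
    """
    tree_left = random_tree(n_seqs, rng)
    tree_right = random_tree(n_seqs, rng) if discordant else tree_left
    root_left = rng.integers(0, 4, size=left_length).astype(np.int8)
    root_right = rng.integers(0, 4, size=right_length).astype(np.int8)
    left = evolve_sequences(tree_left, root_left, rate, rng)
    right = evolve_sequences(tree_right, root_right, rate, rng)
    return [
        _decode(left[i]) + _decode(right[i]) for i in range(n_seqs)
    ]


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------


def simulate_allele_pools(
    config: SimulationConfig,
) -> tuple[AlleleCatalog, dict[str, list[str]]]:
    """Simulate the allele catalog and per-population allele pools.

    Alleles descend from one ancestral coding sequence along a random
    genealogy with per-codon selection classes; optional recombinant alleles
    splice two donors at the configured breakpoint.  Pools are assigned
    sequentially with ``pool_overlap`` sharing between adjacent populations.
    """
    rng = _substreams(config.seed, 5)[0]
    sizes = list(config.alleles_per_population)
    shared: list[int] = []
    for i in range(1, config.n_populations):
        shared.append(int(round(config.pool_overlap * min(sizes[i - 1], sizes[i]))))
    n_unique = sum(sizes) - sum(shared)
    max_distinct = 4 ** (3 * config.n_codons)
    if n_unique > max_distinct:
        raise ValueError("requested more alleles than achievable distinct sequences")

    omega = np.full(config.n_codons, config.neutral_omega)
    for site in config.selected_codons:
        if 1 <= site <= config.n_codons:
            omega[site - 1] = config.selected_omega

    root = _random_coding_root(config.n_codons, rng)
    tree = random_tree(n_unique, rng)
    leaf_seqs = _evolve_with_selection(tree, root, config.tree_scale, omega, rng)
    seqs = [leaf_seqs[i] for i in range(n_unique)]

    if config.recombination_breakpoint and n_unique >= 4:
        cut = int(config.recombination_breakpoint)
        cut = max(3, min(cut, 3 * config.n_codons - 3))
        n_rec = int(round(config.recombinant_fraction * n_unique))
        targets = rng.choice(n_unique, size=n_rec, replace=False)
        for t in targets:
            donors = rng.choice(n_unique, size=2, replace=False)
            candidate = np.concatenate([seqs[donors[0]][:cut], seqs[donors[1]][cut:]])
            if not _has_stop(candidate):
                seqs[t] = candidate

    _ensure_distinct(seqs, omega, config.tree_scale, rng)

    ids = [f"{config.locus_name}*{i + 1:02d}" for i in range(n_unique)]
    catalog = AlleleCatalog(
        locus_name=config.locus_name,
        alleles={a: _decode(s) for a, s in zip(ids, seqs)},
        codon_mode=True,
    )

    pools: dict[str, list[str]] = {}
    cursor = 0
    prev_pool: list[str] = []
    for pop_i, name in enumerate(config.population_names):
        take_shared = shared[pop_i - 1] if pop_i > 0 else 0
        pool = list(prev_pool[-take_shared:]) if take_shared else []
        fresh = sizes[pop_i] - len(pool)
        pool.extend(ids[cursor : cursor + fresh])
        cursor += fresh
        pools[name] = pool
        prev_pool = pool
    return catalog, pools


def _has_stop(seq: np.ndarray) -> bool:
    for start in range(0, seq.size, 3):
        if _CODON_AA[_decode(seq[start : start + 3])] == "*":
            return True
    return False


def _ensure_distinct(
    seqs: list[np.ndarray],
    omega: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> None:
    seen: dict[str, int] = {}
    for i, seq in enumerate(seqs):
        key = _decode(seq)
        guard = 0
        while key in seen:
            seqs[i] = _mutate_selected(seqs[i], 0.5, max(rate, 0.02), omega, rng)
            key = _decode(seqs[i])
            guard += 1
            if guard > 1000:
                raise ValueError("could not generate distinct allele sequences")
        seen[key] = i


def simulate_genotypes(
    pools: dict[str, list[str]],
    config: SimulationConfig,
) -> PopulationGenotypes:
    """Diploid genotypes with Dirichlet frequencies and inbreeding f_is.

    Homozygote i has probability f*p_i + (1-f)*p_i^2 and heterozygote ij has
    (1-f)*2*p_i*p_j, producing the heterozygote deficit observed at loci
    with null alleles when f_is > 0.
    """
    rng = _substreams(config.seed, 5)[1]
    records = []
    for pop_i, (name, pool) in enumerate(pools.items()):
        n_ind = config.diploids_per_population[pop_i]
        if len(pool) == 1:
            freqs = np.array([1.0])
        else:
            freqs = rng.dirichlet(np.full(len(pool), config.freq_concentration))
        for s in range(n_ind):
            if len(pool) == 1 or rng.random() < config.f_is:
                allele = pool[_draw(freqs, rng)]
                pair = (allele, allele)
            else:
                pair = (
                    pool[_draw(freqs, rng)],
                    pool[_draw(freqs, rng)],
                )
            records.append(
                GenotypeRecord(
                    sample_id=f"{name}_{s + 1:03d}",
                    population=name,
                    locus=config.locus_name,
                    allele_a=pair[0],
                    allele_b=pair[1],
                )
            )
    return PopulationGenotypes(records, populations=list(pools))


def _draw(freqs: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(freqs.size, p=freqs))


def simulate_microsatellites(config: SimulationConfig) -> PopulationGenotypes:
    """Independent low-diversity loci shared across populations with drift.

    Per locus, a common base frequency vector is drawn and each population's
    frequencies are Dirichlet-perturbed around it; genotypes are sampled at
    Hardy-Weinberg proportions.  With ``spatial_decay`` > 0 the populations
    drift stepwise along their (linear) landscape order instead, so
    differentiation accumulates with distance (isolation by distance).
    """
    rng = _substreams(config.seed, 5)[2]
    lo, hi = config.microsat_alleles_range
    records = []
    for locus_i in range(config.n_microsat_loci):
        locus = f"msat{locus_i + 1:02d}"
        n_alleles = int(rng.integers(lo, hi + 1))
        allele_names = [str(150 + 2 * a) for a in range(n_alleles)]
        base = rng.dirichlet(np.full(n_alleles, 5.0))
        prev = base
        for pop_i, name in enumerate(config.population_names):
            if n_alleles == 1:
                freqs = np.array([1.0])
            elif config.spatial_decay > 0:
                conc = config.microsat_drift / config.spatial_decay
                freqs = rng.dirichlet(prev * conc + 1e-3)
                prev = freqs
            else:
                freqs = rng.dirichlet(base * config.microsat_drift + 1e-3)
            for s in range(config.diploids_per_population[pop_i]):
                pair = (
                    allele_names[_draw(freqs, rng)],
                    allele_names[_draw(freqs, rng)],
                )
                records.append(
                    GenotypeRecord(
                        sample_id=f"{name}_{s + 1:03d}",
                        population=name,
                        locus=locus,
                        allele_a=pair[0],
                        allele_b=pair[1],
                    )
                )
    return PopulationGenotypes(records, populations=list(config.population_names))


def simulate_landscape(
    config: SimulationConfig,
) -> tuple[dict[str, tuple[float, float]], DistanceMatrixLabeled]:
    """Population coordinates and their great-circle distance matrix."""
    if config.n_populations < 3:
        raise ValueError("need at least three populations for a landscape")
    rng = _substreams(config.seed, 5)[3]
    if config.coordinates is not None:
        coords = {
            name: tuple(coord)
            for name, coord in zip(config.population_names, config.coordinates)
        }
    elif config.spatial_decay > 0:
        # equally spaced along a meridian: distance proportional to the
        # stepwise drift order used by simulate_microsatellites
        coords = {
            name: (-38.5 + 0.45 * i, 176.0)
            for i, name in enumerate(config.population_names)
        }
    else:
        coords = {
            name: (
                float(-38.5 + 2.5 * rng.random()),
                float(175.0 + 3.5 * rng.random()),
            )
            for name in config.population_names
        }
    return coords, geographic_distance_matrix(coords)


def simulate_dataset(config: SimulationConfig) -> dict:
    """All pipeline inputs for one configuration (deterministic per seed)."""
    catalog, pools = simulate_allele_pools(config)
    genotypes = simulate_genotypes(pools, config)
    microsats = simulate_microsatellites(config)
    coords, geo = simulate_landscape(config)
    return {
        "config": config,
        "catalog": catalog,
        "pools": pools,
        "dab_genotypes": genotypes,
        "microsat_genotypes": microsats,
        "coordinates": coords,
        "geographic_distances": geo,
    }
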