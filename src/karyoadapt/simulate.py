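"""Synthetic-data generators for every pipeline input.

The centerpiece is a stochastic simulator of adaptation to chromosomal
instability: a Wright–Fisher-style population in which every chromosome of
every daughter cell missegregates (gains or loses one copy) with a small
per-division probability, fitness is multiplicative over per-chromosome
copy-state effects and pairwise interaction terms, and the population is
periodically bottlenecked to a single clone — emulating serial
single-colony passaging (~10 rounds of ~20 generations). The remaining
generators produce read-depth profiles and BED files conditioned on a
karyotype (Poisson counts), multiplicative colony-size matrices with
planted interaction terms, and arm-level segment tables with optional
focal-event contamination.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeBuild
from .tumor_arms import ArmModel

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_adaptation",
    "expected_read_depth_profile",
    "simulate_read_depth_profile",
    "simulate_read_bed",
    "write_bed",
    "simulate_colony_matrix",
    "simulate_segment_table",
    "write_segments",
    "yeast_genome",
    "config_from_yaml",
]

# S. cerevisiae sacCer3 (R64-1-1) chromosome lengths in bp.
_SACCER3_LENGTHS = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
}


def yeast_genome(basal_ploidy: int = 1, telomere_exclusion: int = 15_000) -> GenomeBuild:
    """The 16-chromosome budding-yeast genome (sacCer3 lengths)."""
    return GenomeBuild(tuple(_SACCER3_LENGTHS.items()), basal_ploidy=basal_ploidy,
                       telomere_exclusion=telomere_exclusion)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Parameters of the CIN-adaptation simulator.

    Attributes
    ----------
    genome
        Chromosome set and basal ploidy of the founding clone.
    missegregation_prob
        Per chromosome per division probability of a copy-number change
        (split evenly between gain and loss). Default 0.02, within the
        per-division missegregation rates measured for strong CIN mutants.
    fitness_effects
        ``{chromosome: {copy: multiplicative factor}}``. Unlisted copy
        states are neutral (factor 1). A factor of 0 is lethal.
    interaction_terms
        ``{(chrom_a, chrom_b): {(copy_a, copy_b): factor}}`` pairwise
        epistatic factors on top of the single-chromosome effects.
    population_size
        Cells carried per generation in the Wright–Fisher update. The
        default (200) is an effective-population-size proxy for growth
        from repeated single-colony bottlenecks, not a colony census size.
    rounds, generations_per_round
        Serial passaging structure: default 10 single-colony bottlenecks
        of ~20 generations each (~200 generations total).
    zero_copy_lethal
        Whether a chromosome at 0 copies kills the cell. Defaults to True
        for haploid genomes, False otherwise (nullisomy from a diploid
        base is still modelled as lethal only if requested).
    max_copy
        Cap on per-chromosome copy number (keeps state tables finite).
    retry_cap
        How many times an extinct replicate (all cells inviable) is
        restarted before being reported as failed.
    """

    genome: GenomeBuild
    missegregation_prob: float = 0.02
    fitness_effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    interaction_terms: Mapping[tuple, Mapping[tuple, float]] = field(default_factory=dict)
    population_size: int = 200
    rounds: int = 10
    generations_per_round: int = 20
    zero_copy_lethal: bool | None = None
    max_copy: int = 6
    retry_cap: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.missegregation_prob <= 1.0:
            raise ValueError("missegregation_prob must be in [0, 1]")
        if self.population_size < 1 or self.rounds < 1 or self.generations_per_round < 1:
            raise ValueError("population_size, rounds and generations_per_round "
                             "must be positive")
        for chrom, states in self.fitness_effects.items():
            if chrom not in self.genome.names:
                raise ValueError(f"fitness effect for unknown chromosome {chrom!r}")
            for copy, s in states.items():
                if s < 0:
                    raise ValueError("fitness factors must be >= 0")
        for pair, states in self.interaction_terms.items():
            for chrom in pair:
                if chrom not in self.genome.names:
                    raise ValueError(f"interaction term for unknown chromosome {chrom!r}")
            for _, eps in states.items():
                if eps < 0:
                    raise ValueError("interaction factors must be >= 0")

    @property
    def lethal_zero(self) -> bool:
        if self.zero_copy_lethal is None:
            return self.genome.basal_ploidy == 1
        return self.zero_copy_lethal


class SimulatedCohort(NamedTuple):
    """Result of :func:`simulate_adaptation`.

    ``karyotypes``: replicates x chromosomes integer copy matrix (one final
    clone per replicate). ``lineage``: (replicates, rounds, chromosomes)
    array of the bottleneck clone after each round. ``retries``: restarts
    per replicate due to extinction. ``failed``: replicates still extinct
    after the retry cap (their karyotype rows are the last dead state).
    """

    karyotypes: pd.DataFrame
    lineage: np.ndarray
    retries: np.ndarray
    failed: np.ndarray


def _fitness_tables(config: SimulationConfig):
    names = config.genome.names
    C, M = len(names), config.max_copy
    s_table = np.ones((C, M + 1))
    if config.lethal_zero:
        s_table[:, 0] = 0.0
    for chrom, states in config.fitness_effects.items():
        i = names.index(chrom)
        for copy, s in states.items():
            if 0 <= copy <= M:
                s_table[i, copy] = s
    pair_tables = []
    for (a, b), states in config.interaction_terms.items():
        i, j = names.index(a), names.index(b)
        tbl = np.ones((M + 1, M + 1))
        for (ca, cb), eps in states.items():
            if 0 <= ca <= M and 0 <= cb <= M:
                tbl[ca, cb] = eps
        pair_tables.append((i, j, tbl))
    return s_table, pair_tables


def _population_fitness(K: np.ndarray, s_table: np.ndarray, pair_tables) -> np.ndarray:
    F = np.ones(K.shape[:-1])
    for c in range(K.shape[-1]):
        F *= s_table[c][K[..., c]]
    for i, j, tbl in pair_tables:
        F *= tbl[K[..., i], K[..., j]]
    return F


def _run_batch(config: SimulationConfig, n_rep: int, rng: np.random.Generator):
    """One vectorized pass over ``n_rep`` replicate lineages. Returns the
    per-round lineage array and a per-replicate extinction mask."""
    genome = config.genome
    C = len(genome.names)
    N = config.population_size
    m = config.missegregation_prob
    s_table, pair_tables = _fitness_tables(config)
    K = np.full((n_rep, N, C), genome.basal_ploidy, dtype=np.int8)
    extinct = np.zeros(n_rep, dtype=bool)
    lineage = np.zeros((n_rep, config.rounds, C), dtype=np.int8)
    rep_idx = np.arange(n_rep)
    for rnd in range(config.rounds):
        for _ in range(config.generations_per_round):
            # missegregation during the divisions that produce this generation
            if m > 0:
                u = rng.random(K.shape)
                np.add(K, (u < m / 2).astype(np.int8), out=K)
                np.subtract(K, (u >= 1 - m / 2).astype(np.int8), out=K)
                np.clip(K, 0, config.max_copy, out=K)
            # viability selection + resampling proportional to fitness
            F = _population_fitness(K, s_table, pair_tables)
            tot = F.sum(axis=1)
            extinct |= tot == 0
            F[extinct] = 1.0             # dead replicates resample uniformly;
            tot = F.sum(axis=1)          # their output is discarded/retried
            cum = np.cumsum(F, axis=1) / tot[:, None]
            cum[:, -1] = 1.0
            u = rng.random((n_rep, N))
            flat_cum = (cum + rep_idx[:, None]).ravel()
            flat_u = (u * (1 - 1e-12) + rep_idx[:, None]).ravel()
            picks = np.searchsorted(flat_cum, flat_u, side="right")
            picks = (picks - rep_idx.repeat(N) * N).reshape(n_rep, N)
            np.clip(picks, 0, N - 1, out=picks)
            K = np.take_along_axis(K, picks[:, :, None], axis=1)
        # single-colony bottleneck: one cell picked uniformly at random,
        # i.e. clones are picked proportional to their frequency
        chosen = rng.integers(0, N, size=n_rep)
        clone = K[rep_idx, chosen]
        lineage[:, rnd, :] = clone
        K = np.repeat(clone[:, None, :], N, axis=1)
    return lineage, extinct


def simulate_adaptation(config: SimulationConfig, replicates: int,
                        seed) -> SimulatedCohort:
    """Simulate ``replicates`` independent adaptation lineages.

    Each replicate starts from a euploid clone, evolves through
    ``rounds x generations_per_round`` Wright–Fisher generations with
    missegregation and multiplicative selection, and is bottlenecked to a
    single clone after each round. The final bottleneck clone of each
    replicate is one cohort karyotype. Replicates that go extinct (every
    cell inviable) are restarted with a fresh random stream up to
    ``retry_cap`` times.
    """
    rng = _rng(seed)
    lineage, extinct = _run_batch(config, replicates, rng)
    retries = np.zeros(replicates, dtype=np.int64)
    attempt = 0
    while extinct.any() and attempt < config.retry_cap:
        attempt += 1
        idx = np.flatnonzero(extinct)
        retries[idx] += 1
        sub_lineage, sub_extinct = _run_batch(config, len(idx), rng)
        lineage[idx] = sub_lineage
        extinct[idx] = sub_extinct
    karyotypes = pd.DataFrame(
        lineage[:, -1, :].astype(np.int64),
        index=[f"rep{i:03d}" for i in range(replicates)],
        columns=config.genome.names,
    )
    return SimulatedCohort(karyotypes=karyotypes, lineage=lineage,
                           retries=retries, failed=extinct)


# ---------------------------------------------------------------------------
# read-count generators


def expected_read_depth_profile(karyotype, genome: GenomeBuild,
                                depth: float) -> pd.DataFrame:
    """Noise-free read-depth profile: counts exactly proportional to the
    planted karyotype (``depth`` = reads per bp at euploid copy number)."""
    copies = _karyotype_array(karyotype, genome)
    usable = genome.usable_lengths
    counts = depth * usable * copies / genome.basal_ploidy
    return pd.DataFrame({
        "chromosome": genome.names,
        "length": genome.lengths,
        "usable_length": usable,
        "read_count": counts,
        "density": counts / usable,
    })


def simulate_read_depth_profile(karyotype, genome: GenomeBuild, depth: float,
                                seed) -> pd.DataFrame:
    """Poisson read-depth profile conditioned on a karyotype.

    Per chromosome, ``read_count ~ Poisson(depth * usable_length * copy /
    ploidy)`` with ``depth`` in reads per bp for a euploid chromosome.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed)
    copies = _karyotype_array(karyotype, genome)
    usable = genome.usable_lengths
    lam = depth * usable * copies / genome.basal_ploidy
    counts = rng.poisson(lam)
    return pd.DataFrame({
        "chromosome": genome.names,
        "length": genome.lengths,
        "usable_length": usable,
        "read_count": counts,
        "density": counts / usable,
    })


def simulate_read_bed(karyotype, genome: GenomeBuild, depth: float, seed,
                      read_length: int = 50) -> pd.DataFrame:
    """Simulate aligned read positions as BED intervals.

    Per chromosome the read count is Poisson with mean ``depth * length *
    copy / ploidy`` and start positions are uniform; reads have a fixed
    length. Deterministic given (parameters, seed).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed)
    copies = _karyotype_array(karyotype, genome)
    frames = []
    for (name, length), copy in zip(genome.chromosomes, copies):
        n = rng.poisson(depth * length * copy / genome.basal_ploidy)
        starts = np.sort(rng.integers(0, max(1, length - read_length), size=n))
        frames.append(pd.DataFrame({
            "chrom": name,
            "start": starts,
            "end": np.minimum(starts + read_length, length),
        }))
    return pd.concat(frames, ignore_index=True)


def _karyotype_array(karyotype, genome: GenomeBuild) -> np.ndarray:
    if isinstance(karyotype, pd.Series):
        karyotype = karyotype.reindex(genome.names)
        if karyotype.isna().any():
            raise ValueError("karyotype missing chromosomes of the genome build")
        return karyotype.to_numpy(dtype=float)
    arr = np.asarray(karyotype, dtype=float)
    if arr.shape != (len(genome.names),):
        raise ValueError("karyotype length does not match genome build")
    return arr


def write_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# colony-size generator


def simulate_colony_matrix(
    chromosomes: Iterable[str],
    single_effects: Mapping[str, float],
    interactions: Mapping[tuple, float],
    noise_sigma: float = 0.1,
    seed=None,
    base_size: float = 1.0,
    diagonal_missing: bool = True,
) -> pd.DataFrame:
    """Double-disome colony-size matrix with planted interactions.

    ``size[a][b] = base * g_a * g_b * eps_ab * exp(Normal(0, sigma))``
    where ``g`` are single-disome growth factors and ``eps`` pairwise
    interaction factors (default 1, i.e. no interaction). The diagonal
    (the same chromosome in both marker orientations) is left missing by
    default, as in real double-disome panels. Sizes in mm^2.
    """
    rng = _rng(seed)
    chroms = list(chromosomes)
    g = np.array([single_effects.get(c, 1.0) for c in chroms])
    if np.any(g <= 0) or base_size <= 0:
        raise ValueError("growth factors and base size must be positive")
    eps = np.ones((len(chroms), len(chroms)))
    for (a, b), e in interactions.items():
        if e <= 0:
            raise ValueError("interaction factors must be positive")
        i, j = chroms.index(a), chroms.index(b)
        eps[i, j] = eps[j, i] = e
    noise = np.exp(rng.normal(0.0, noise_sigma, size=eps.shape)) \
        if noise_sigma > 0 else 1.0
    M = base_size * np.outer(g, g) * eps * noise
    if diagonal_missing:
        np.fill_diagonal(M, np.nan)
    return pd.DataFrame(M, index=chroms, columns=chroms)


# ---------------------------------------------------------------------------
# segment-table generator


def simulate_segment_table(
    arm_calls: pd.DataFrame,
    arms: ArmModel,
    noise_sigma: float = 0.0,
    focal_rate: float = 0.0,
    seed=None,
    max_pieces: int = 5,
    focal_fraction: float = 0.1,
    focal_amplitude: float = 4.0,
) -> pd.DataFrame:
    """Arm-level SEG records conditioned on planted arm calls.

    Each arm is split into 1..``max_pieces`` contiguous segments whose
    value is ``log2((2 + call) / 2) + Normal(0, noise_sigma)``. With
    probability ``focal_rate`` per (sample, arm), a short high-amplitude
    focal segment (``focal_fraction`` of the arm at ``focal_amplitude``
    above baseline) is injected — sized so that the arm's weighted mean
    and median separate by more than the standard 0.2 exclusion gap,
    exercising the focal-contamination filter.
    """
    rng = _rng(seed)
    rows = []
    for sample in arm_calls.index:
        for arm_name in arm_calls.columns:
            call = int(arm_calls.loc[sample, arm_name])
            iv = arms.interval(arm_name)
            chrom = arm_name[:-1]
            base_value = float(np.log2((2 + call) / 2))
            n_pieces = int(rng.integers(1, max_pieces + 1))
            cuts = np.sort(rng.integers(iv.start + 1, iv.end, size=n_pieces - 1)) \
                if n_pieces > 1 else np.array([], dtype=np.int64)
            bounds = np.concatenate(([iv.start], cuts, [iv.end]))
            focal = rng.random() < focal_rate
            if focal:
                flen = max(1, int(focal_fraction * (iv.end - iv.start)))
                fstart = int(rng.integers(iv.start, iv.end - flen + 1))
                fend = fstart + flen
                bounds = np.unique(np.concatenate((bounds, [fstart, fend])))
            for s, e in zip(bounds[:-1], bounds[1:]):
                if e <= s:
                    continue
                value = base_value + (rng.normal(0.0, noise_sigma)
                                      if noise_sigma > 0 else 0.0)
                if focal and s >= fstart and e <= fend:
                    value = base_value + focal_amplitude
                rows.append((sample, chrom, int(s), int(e), value))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"])


def write_segments(segments: pd.DataFrame, path) -> None:
    """Write a segment table in SEG format (tab-separated with header)."""
    out = segments.rename(columns={
        "sample": "Sample", "chrom": "Chromosome", "start": "Start",
        "end": "End", "value": "Segment_Mean",
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# declarative configuration


def config_from_yaml(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file.

    Expected keys mirror the dataclass fields; the genome block is either
    ``{chromosomes: [[name, length], ...], ploidy: 1, telomere_exclusion:
    15000}`` or ``{preset: yeast, ploidy: 1}``. Interaction terms are a
    list of ``{pair: [a, b], copies: [ca, cb], factor: f}`` entries.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gblock = raw.get("genome", {"preset": "yeast"})
    ploidy = int(gblock.get("ploidy", 1))
    tel = int(gblock.get("telomere_exclusion", 15_000))
    if gblock.get("preset") == "yeast":
        genome = yeast_genome(basal_ploidy=ploidy, telomere_exclusion=tel)
    else:
        genome = GenomeBuild(
            tuple((str(n), int(l)) for n, l in gblock["chromosomes"]),
            basal_ploidy=ploidy, telomere_exclusion=tel,
        )
    fitness = {
        str(chrom): {int(c): float(s) for c, s in states.items()}
        for chrom, states in (raw.get("fitness_effects") or {}).items()
    }
    interactions: dict[tuple, dict[tuple, float]] = {}
    for entry in raw.get("interaction_terms") or []:
        a, b = entry["pair"]
        ca, cb = entry["copies"]
        interactions.setdefault((str(a), str(b)), {})[(int(ca), int(cb))] = \
            float(entry["factor"])
    kwargs = {}
    for key in ("missegregation_prob", "population_size", "rounds",
                "generations_per_round", "zero_copy_lethal", "max_copy",
                "retry_cap"):
        if key in raw:
            kwargs[key] = raw[key]
    return SimulationConfig(genome=genome, fitness_effects=fitness,
                            interaction_terms=interactions, **kwargs)
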