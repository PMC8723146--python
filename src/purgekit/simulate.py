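"""Forward individual-based simulator of bottlenecked populations.

The simulator produces pedigrees in which purging has an opportunity to act:
a large base population accumulates recessive deleterious mutations under
mutation-selection(-drift) balance, then is bottlenecked to a small census in
which inbreeding exposes the recessives to selection.  Per-individual fitness
and inbreeding load are recorded, so coefficient-based predictions of load
decline can be checked against a known truth.

The model is diploid with free recombination (every mutation segregates
independently), soft selection (parents are sampled with probability
proportional to fitness; census sizes are fixed by the schedule), and an
infinite-sites mutation process: each new mutation is unique, with selection
coefficient s and dominance h drawn from the configured distributions.
Fitness is multiplicative across loci: W = prod(1 - h s) over heterozygous
sites times prod(1 - s) over homozygous sites.

The recorded pedigree starts at the final base-population cohort (the
founders, time 0); the burn-in only shapes the founders' mutational load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UNKNOWN, read_pedigree, write_pedigree

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_population",
    "individual_load",
    "export_fixture",
    "random_pedigree",
    "PRESETS",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulator configuration.

    Parameters
    ----------
    N_base, t_base : int
        Census and duration (generations) of the base population burn-in.
    N_bottleneck, t_bottleneck : int
        Census and duration of the bottleneck; the recorded pedigree spans
        the last base cohort (founders) plus these generations.
    U : float
        Genomic deleterious mutation rate per diploid offspring per
        generation (Poisson).
    s_dist : tuple
        ("point", s) or ("gamma", shape, mean); selection coefficients are
        truncated to [0, 1], s = 1 being lethal.
    lethal_fraction : float
        Extra point mass of lethals (s = 1) mixed into s_dist.
    h_rule : tuple
        ("constant", h), or ("decreasing", k): h = 0.5 * exp(-k * s), the
        common observation that large-effect mutations are more recessive.
    mating : str
        "random" (parents drawn independently, selfing possible — the ideal
        Wright-Fisher reference), "random_no_selfing" (default), or
        "monogamous" (fitness-ranked pair formation, offspring spread over
        pairs).
    seed : int
        Master seed; identical config gives bit-identical results.
    """

    N_base: int = 200
    t_base: int = 200
    N_bottleneck: int = 25
    t_bottleneck: int = 50
    U: float = 0.5
    s_dist: tuple = ("point", 1.0)
    lethal_fraction: float = 0.0
    h_rule: tuple = ("constant", 0.0)
    mating: str = "random_no_selfing"
    seed: int = 0

    def __post_init__(self):
        if self.N_base < 2 or self.N_bottleneck < 2:
            raise ValueError("census sizes must be >= 2")
        if self.t_base < 0 or self.t_bottleneck < 1:
            raise ValueError("invalid generation counts")
        if self.U < 0:
            raise ValueError("mutation rate U must be >= 0")
        if not 0.0 <= self.lethal_fraction <= 1.0:
            raise ValueError("lethal_fraction must be a probability")
        if self.s_dist[0] not in {"point", "gamma"}:
            raise ValueError(f"unknown s distribution {self.s_dist[0]!r}")
        if self.h_rule[0] not in {"constant", "decreasing"}:
            raise ValueError(f"unknown h rule {self.h_rule[0]!r}")
        if self.mating not in {"random", "random_no_selfing", "monogamous"}:
            raise ValueError(f"unknown mating scheme {self.mating!r}")


#: Ready-made configurations.  "purging-favorable" carries highly deleterious
#: fully recessive (lethal) mutations at a high genomic rate, the regime in
#: which opportunity-of-purging coefficients are expected to be informative.
PRESETS: dict[str, SimConfig] = {
    "purging-favorable": SimConfig(),
    "neutral": SimConfig(U=0.0, mating="random"),
}


@dataclass
class SimResult:
    """Simulator output: pedigree with fitness and load, plus trajectories."""

    pedigree: Pedigree  # sorted; columns id, sire, dam, time, fitness, B
    trajectory: pd.DataFrame  # generation, census, mean_W, mean_B (mean_F once computed)
    config: SimConfig
    B0: float  # mean inbreeding load of the founder cohort

    @property
    def fitness(self) -> np.ndarray:
        return self.pedigree.df["fitness"].to_numpy(dtype=float)

    @property
    def load(self) -> np.ndarray:
        return self.pedigree.df["B"].to_numpy(dtype=float)

    def provenance(self) -> dict:
        prov = asdict(self.config)
        prov["B0"] = self.B0
        return prov


def individual_load(het: list[tuple[float, float]]) -> float:
    """Inbreeding load B of one genotype, in haploid lethal equivalents.

    ``het`` lists (s, h) for the heterozygous sites.  Making a heterozygous
    site homozygous at random (one of the two alleles drawn) changes log
    fitness by -s(1 - 2h)/2 per site in expectation, so
    B = 1/2 * sum s (1 - 2h).  Homozygous sites contribute nothing: they are
    already expressed.
    """
    return 0.5 * sum(s * (1.0 - 2.0 * h) for s, h in het)


def _draw_mutations(rng: np.random.Generator, config: SimConfig, count: int):
    """Draw (s, h) for ``count`` new mutations."""
    if config.s_dist[0] == "point":
        s = np.full(count, float(config.s_dist[1]))
    else:
        _, shape, mean = config.s_dist
        s = rng.gamma(shape, mean / shape, size=count)
    s = np.clip(s, 0.0, 1.0)
    if config.lethal_fraction > 0:
        s[rng.random(count) < config.lethal_fraction] = 1.0
    kind, par = config.h_rule
    if kind == "constant":
        h = np.full(count, float(par))
    else:
        h = 0.5 * np.exp(-par * s)
    return s, h


class _Genome:
    """Mutation-id lists for one diploid individual."""

    __slots__ = ("het", "hom")

    def __init__(self, het: np.ndarray, hom: np.ndarray):
        self.het = het  # heterozygous mutation ids, sorted
        self.hom = hom  # homozygous mutation ids, sorted


def _fitness(genome: _Genome, s_of: np.ndarray, h_of: np.ndarray) -> float:
    w = 1.0
    if genome.het.size:
        w *= float(np.prod(1.0 - h_of[genome.het] * s_of[genome.het]))
    if genome.hom.size:
        w *= float(np.prod(1.0 - s_of[genome.hom]))
    return w


def _load(genome: _Genome, s_of: np.ndarray, h_of: np.ndarray) -> float:
    if genome.het.size == 0:
        return 0.0
    s = s_of[genome.het]
    h = h_of[genome.het]
    return float(0.5 * np.sum(s * (1.0 - 2.0 * h)))


def _gamete(rng: np.random.Generator, genome: _Genome) -> np.ndarray:
    if genome.het.size:
        chosen = genome.het[rng.random(genome.het.size) < 0.5]
    else:
        chosen = genome.het
    return np.concatenate([genome.hom, chosen])


def _mate_pairs(rng, W, N_off, mating):
    """Return (sires, dams): parent indices for N_off offspring."""
    total = W.sum()
    if total <= 0:
        raise RuntimeError("population fitness collapsed to zero")
    p = W / total
    n_par = len(W)
    if mating == "random":
        sires = rng.choice(n_par, size=N_off, p=p)
        dams = rng.choice(n_par, size=N_off, p=p)
    elif mating == "random_no_selfing":
        sires = rng.choice(n_par, size=N_off, p=p)
        dams = rng.choice(n_par, size=N_off, p=p)
        for k in range(N_off):
            while dams[k] == sires[k]:
                dams[k] = rng.choice(n_par, p=p)
    else:  # monogamous: fitness-weighted pairing without replacement
        order = rng.choice(n_par, size=n_par, replace=False, p=p)
        n_pairs = n_par // 2
        pair_idx = rng.integers(0, n_pairs, size=N_off)
        sires = order[2 * pair_idx]
        dams = order[2 * pair_idx + 1]
    return sires, dams


def simulate_population(config: SimConfig) -> SimResult:
    """Run the burn-in + bottleneck simulation described by ``config``.

    Returns a :class:`SimResult` whose pedigree records the final base cohort
    as founders (time 0) and every bottleneck cohort (time 1..t_bottleneck),
    with per-individual fitness W and inbreeding load B.
    """
    rng = np.random.default_rng(config.seed)
    s_of = np.empty(0)
    h_of = np.empty(0)
    empty = np.empty(0, dtype=np.int64)
    pop = [_Genome(empty, empty) for _ in range(config.N_base)]

    def next_generation(pop, N_off):
        nonlocal s_of, h_of
        W = np.array([_fitness(g, s_of, h_of) for g in pop])
        sires, dams = _mate_pairs(rng, W, N_off, config.mating)
        counts = rng.poisson(config.U, size=N_off)
        new_s, new_h = _draw_mutations(rng, config, int(counts.sum()))
        base_id = s_of.size
        s_of = np.concatenate([s_of, new_s])
        h_of = np.concatenate([h_of, new_h])
        offspring = []
        mut_cursor = base_id
        for k in range(N_off):
            g1 = _gamete(rng, pop[sires[k]])
            g2 = _gamete(rng, pop[dams[k]])
            hom = np.intersect1d(g1, g2)
            het = np.setdiff1d(np.concatenate([g1, g2]), hom)
            fresh = np.arange(mut_cursor, mut_cursor + counts[k], dtype=np.int64)
            mut_cursor += counts[k]
            het = np.concatenate([het, fresh])
            het.sort()
            offspring.append(_Genome(het, hom))
        return offspring, sires, dams

    for _ in range(config.t_base):
        pop, _, _ = next_generation(pop, config.N_base)

    # recorded pedigree: founders = final base cohort
    rows = []
    times = []
    fitness = []
    load = []
    names = [f"G0_{k}" for k in range(len(pop))]
    for k, g in enumerate(pop):
        rows.append((names[k], UNKNOWN, UNKNOWN))
        times.append(0)
        fitness.append(_fitness(g, s_of, h_of))
        load.append(_load(g, s_of, h_of))

    # first bottleneck cohort descends from the founders
    current = pop
    cur_names = names
    for t in range(1, config.t_bottleneck + 1):
        current, sires, dams = next_generation(current, config.N_bottleneck)
        new_names = [f"G{t}_{k}" for k in range(config.N_bottleneck)]
        for k, g in enumerate(current):
            rows.append((new_names[k], cur_names[sires[k]], cur_names[dams[k]]))
            times.append(t)
            fitness.append(_fitness(g, s_of, h_of))
            load.append(_load(g, s_of, h_of))
        cur_names = new_names

    df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    df["time"] = times
    df["fitness"] = fitness
    df["B"] = load
    ped = Pedigree(df)

    traj = (
        df.groupby("time")
        .agg(census=("id", "size"), mean_W=("fitness", "mean"), mean_B=("B", "mean"))
        .reset_index()
        .rename(columns={"time": "generation"})
    )
    B0 = float(df.loc[df["time"] == 0, "B"].mean())
    return SimResult(pedigree=ped, trajectory=traj, config=config, B0=B0)


def export_fixture(result: SimResult, path) -> dict[str, Path]:
    """Write pedigree TSV, trajectory TSV and provenance JSON under ``path``.

    The pedigree file (columns id, sire, dam, time, fitness, B; unknown
    parents as NA) round-trips losslessly through :func:`read_pedigree`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "pedigree": path / "pedigree.tsv",
        "trajectory": path / "trajectory.tsv",
        "provenance": path / "provenance.json",
    }
    try:
        write_pedigree(result.pedigree, files["pedigree"])
        result.trajectory.to_csv(files["trajectory"], sep="\t", index=False)
        files["provenance"].write_text(json.dumps(result.provenance(), indent=2))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write simulation fixture under {path}: {exc}") from exc
    return files


def random_pedigree(
    n: int,
    seed: int,
    founder_prob: float = 0.25,
    missing_prob: float = 0.05,
) -> Pedigree:
    """A random valid sorted pedigree for testing and oracle comparisons.

    Individual i is a founder with probability ``founder_prob`` (the first two
    always are); otherwise its parents are drawn uniformly among earlier
    individuals (selfing arises when the draws coincide), with each parent
    link independently unknown with probability ``missing_prob``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        name = f"I{i}"
        if i < 2 or rng.random() < founder_prob:
            rows.append((name, UNKNOWN, UNKNOWN))
            continue
        sire = f"I{rng.integers(0, i)}" if rng.random() > missing_prob else UNKNOWN
        dam = f"I{rng.integers(0, i)}" if rng.random() > missing_prob else UNKNOWN
        rows.append((name, sire, dam))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))
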