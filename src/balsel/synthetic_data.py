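"""Forward Wright–Fisher generators for pipeline inputs.

Two generators cover the statistical structure the analysis assumes:

* :func:`simulate_two_pop_haplotypes` — a forward diploid Wright–Fisher
  simulation with infinite-sites mutation and uniform recombination.  After
  a neutral burn-in of ≥10N generations a derived allele is placed at a
  target site and the population is split into two daughters that evolve
  independently; the target experiences symmetric overdominance (genotype
  fitnesses 1 : 1+s_het : 1, equilibrium frequency 0.5).  Output is a
  phased diploid sample from each daughter plus a truth record.

* :func:`simulate_epistatic_couples` — two-locus genotype samples for
  couples under epistatic fertility selection: couples drawn at
  Hardy–Weinberg, offspring contribution weighted 1 + s_match for
  designated compatible genotype pairs, realized pairs tabulated 3×3.

Forward (rather than coalescent) simulation keeps selection and epistasis
first-class and the machinery self-contained; population sizes are small
and rates rescaled accordingly (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .haplotype_io import PhasedHaplotypeSet

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Forward-simulation parameters (rates are per generation).

    Defaults describe a 20-fold rescaled human-like gene region: N=500
    diploids with mu=rho=5e-7 per bp gives θ = ρ = 4Nμ ≈ 1e-3 per bp, and
    split_generations=500 is a divergence time of 0.5 coalescent units
    (t·2N generations), the out-of-Africa-scale scenario.
    """

    N: int = 500
    mu: float = 5e-7
    rho: float = 5e-7
    L: int = 20_000
    split_generations: int = 500
    s_het: float = 0.05
    seed: int | None = None
    burn_in_factor: int = 10          # burn-in = burn_in_factor · N generations
    n_sample: int = 50                # diploids sampled per population
    target_init: float | str = 0.5    # initial derived frequency, or "single_copy"
    reinject_lost_target: bool = True
    max_target_attempts: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.N < 10:
            raise ValueError("N must be at least 10")
        for r in (self.mu, self.rho):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_sample > self.N:
            raise ValueError("cannot sample more diploids than the population holds")


class TargetLostError(RuntimeError):
    """The target allele was lost and re-injection was disabled/exhausted."""


class _Population:
    """2N haplotypes over a dynamic set of segregating sites."""

    def __init__(self, N: int, positions: np.ndarray, matrix: np.ndarray):
        self.N = N
        self.positions = positions          # float positions in (0, L)
        self.matrix = matrix                # (2N, S) int8

    def copy(self) -> "_Population":
        return _Population(self.N, self.positions.copy(), self.matrix.copy())

    def freq(self, col: int) -> float:
        return float(self.matrix[:, col].mean())


def _step(
    pop: _Population,
    rng: np.random.Generator,
    mu: float,
    rho: float,
    L: int,
    s_het: float,
    target_pos: float | None,
) -> None:
    """One non-overlapping Wright-Fisher generation (in place)."""
    N = pop.N
    two_n = 2 * N
    H = pop.matrix
    pos = pop.positions

    # viability selection on the target genotype: 1, 1+s, 1
    probs = None
    if target_pos is not None and s_het != 0.0:
        col = _find_col(pop, target_pos)
        if col is not None:
            g = H[0::2, col].astype(int) + H[1::2, col].astype(int)
            w = np.where(g == 1, 1.0 + s_het, 1.0)
            probs = w / w.sum()

    parents = rng.choice(N, size=(N, 2), p=probs)     # mother, father per child
    gamete_parent = parents.reshape(-1)               # 2N gametes
    start_hap = rng.integers(0, 2, size=two_n)
    rows = 2 * gamete_parent + start_hap

    # recombination: each breakpoint flips the source haplotype for every
    # column to its right; parity of flips selects the parental strand
    n_cross = rng.poisson(rho * L, size=two_n)
    n_tot = int(n_cross.sum())
    if n_tot and len(pos):
        break_gamete = np.repeat(np.arange(two_n), n_cross)
        break_pos = rng.uniform(0, L, size=n_tot)
        delta = np.zeros((two_n, len(pos) + 1), dtype=np.int32)
        np.add.at(delta, (break_gamete, np.searchsorted(pos, break_pos)), 1)
        use_other = (np.cumsum(delta[:, :-1], axis=1) % 2).astype(bool)
        other_rows = 2 * gamete_parent + (1 - start_hap)
        child = np.where(use_other, H[other_rows], H[rows])
    else:
        child = H[rows].copy()

    # infinite-sites mutation: each hit is a brand-new position
    n_mut = rng.poisson(two_n * mu * L)
    if n_mut:
        existing = set(pop.positions.tolist())
        new_pos = []
        while len(new_pos) < n_mut:
            cand = rng.uniform(0, L, size=n_mut - len(new_pos))
            for c in cand:
                if c not in existing:
                    existing.add(c)
                    new_pos.append(c)
        targets = rng.integers(0, two_n, size=n_mut)
        add = np.zeros((two_n, n_mut), dtype=np.int8)
        add[targets, np.arange(n_mut)] = 1
        child = np.concatenate([child, add], axis=1)
        pos = np.concatenate([pos, np.array(new_pos)])
        order = np.argsort(pos)
        pos = pos[order]
        child = child[:, order]

    pop.matrix = child
    pop.positions = pos


def _find_col(pop: _Population, position: float) -> int | None:
    i = int(np.searchsorted(pop.positions, position))
    if i < len(pop.positions) and pop.positions[i] == position:
        return i
    return None


def _sync(pops: list[_Population]) -> None:
    """Align all populations on the union of their site registries."""
    union = np.unique(np.concatenate([p.positions for p in pops]))
    for p in pops:
        if len(p.positions) == len(union):
            continue
        fill = np.zeros((p.matrix.shape[0], len(union)), dtype=np.int8)
        idx = np.searchsorted(union, p.positions)
        fill[:, idx] = p.matrix
        p.matrix = fill
        p.positions = union.copy()


def _cleanup(pops: list[_Population], target_pos: float | None) -> None:
    """Drop columns lost or fixed in every population (target kept)."""
    total = sum(p.matrix.sum(axis=0) for p in pops)
    copies = sum(2 * p.N for p in pops)
    keep = (total > 0) & (total < copies)
    if target_pos is not None:
        col = _find_col(pops[0], target_pos)
        if col is not None:
            keep[col] = True
    idx = np.flatnonzero(keep)
    for p in pops:
        p.matrix = p.matrix[:, idx]
        p.positions = p.positions[idx]


def simulate_two_pop_haplotypes(
    config: SimConfig,
) -> tuple[PhasedHaplotypeSet, dict]:
    """Two diverged populations with a balanced target polymorphism.

    Returns (hapset, truth).  The hapset holds ``2·n_sample`` phased
    diploids per population (groups ``pop1``/``pop2``); monomorphic columns
    of the combined sample are dropped.  The truth record carries the
    target position and its frequency trajectory in each population.
    """
    rng = np.random.default_rng(config.seed)
    N, L = config.N, config.L

    pop = _Population(
        N, np.empty(0, dtype=float), np.zeros((2 * N, 0), dtype=np.int8)
    )
    burn_in = config.burn_in_factor * N
    for gen in range(burn_in):
        _step(pop, rng, config.mu, config.rho, L, 0.0, None)
        if gen % 25 == 24:
            _cleanup([pop], None)

    # place the target derived allele at the midpoint of the region
    attempts = 0
    target_pos = L / 2.0
    while True:
        attempts += 1
        col = int(np.searchsorted(pop.positions, target_pos))
        pop.positions = np.insert(pop.positions, col, target_pos)
        new_col = np.zeros((2 * N, 1), dtype=np.int8)
        if config.target_init == "single_copy":
            carriers = rng.integers(0, 2 * N, size=1)
        else:
            k = int(round(float(config.target_init) * 2 * N))
            carriers = rng.choice(2 * N, size=k, replace=False)
        new_col[carriers, 0] = 1
        pop.matrix = np.concatenate(
            [pop.matrix[:, :col], new_col, pop.matrix[:, col:]], axis=1
        )

        pops = [pop.copy(), pop.copy()]
        traj: list[list[float]] = [[], []]
        lost = False
        for gen in range(config.split_generations):
            for k in (0, 1):
                _step(pops[k], rng, config.mu, config.rho, L, config.s_het,
                      target_pos)
            _sync(pops)
            tcol = _find_col(pops[0], target_pos)
            for k in (0, 1):
                traj[k].append(pops[k].freq(tcol))
            if gen % 25 == 24:
                _cleanup(pops, target_pos)
            seg = [
                0 < pops[k].matrix[:, _find_col(pops[k], target_pos)].sum() < 2 * N
                for k in (0, 1)
            ]
            if not any(seg) and config.s_het > 0:
                lost = True
                break
        if not lost or not config.reinject_lost_target:
            break
        # remove the dead target column from the ancestral pool and retry
        tcol = _find_col(pop, target_pos)
        pop.positions = np.delete(pop.positions, tcol)
        pop.matrix = np.delete(pop.matrix, tcol, axis=1)
        if attempts >= config.max_target_attempts:
            raise TargetLostError(
                f"target allele lost in {attempts} consecutive attempts"
            )
    _sync(pops)

    # sample without replacement from each daughter
    samples: list[str] = []
    population: dict[str, str] = {}
    rows_all: list[np.ndarray] = []
    for k, p in enumerate(pops, start=1):
        chosen = rng.choice(p.N, size=config.n_sample, replace=False)
        rows = np.array([r for i in chosen for r in (2 * i, 2 * i + 1)])
        rows_all.append(p.matrix[rows])
        for i in range(config.n_sample):
            name = f"pop{k}_s{i:03d}"
            samples.append(name)
            population[name] = f"pop{k}"
    matrix = np.concatenate(rows_all, axis=0)

    # integer, unique bp coordinates for VCF compatibility
    bp = np.round(pops[0].positions * 1.0).astype(np.int64) + 1
    for j in range(1, len(bp)):
        if bp[j] <= bp[j - 1]:
            bp[j] = bp[j - 1] + 1

    counts = matrix.sum(axis=0)
    poly = (counts > 0) & (counts < matrix.shape[0])
    target_idx = _find_col(pops[0], target_pos)
    target_in_sample = bool(target_idx is not None and poly[target_idx])

    ref = _BASES[rng.integers(0, 4, size=poly.sum())]
    alt_shift = rng.integers(1, 4, size=poly.sum())
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]

    hapset = PhasedHaplotypeSet(
        samples=samples,
        population=population,
        chromosome="sim1",
        positions=bp[poly],
        ref_allele=list(ref),
        alt_allele=list(alt),
        haplotype_matrix=matrix[:, poly],
    )
    truth = {
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "target_position": int(bp[target_idx]) if target_idx is not None else None,
        "target_in_sample": target_in_sample,
        "target_attempts": attempts,
        "target_trajectory_pop1": traj[0],
        "target_trajectory_pop2": traj[1],
        "final_target_freq_pop1": traj[0][-1] if traj[0] else None,
        "final_target_freq_pop2": traj[1][-1] if traj[1] else None,
    }
    return hapset, truth


# ---------------------------------------------------------------------------
# Epistatic fertility selection on couple genotypes


@dataclass
class EpistasisConfig:
    """Couple-sampling parameters for the two-locus fertility model.

    The default sample size matches a large founder-population study scale
    (1,415 couples); ``match_pairs`` designates the compatible genotype
    combinations whose offspring contribution is weighted 1 + s_match.
    """

    n_couples: int = 1_415
    freq_locus1: float = 0.5
    freq_locus2: float = 0.5
    s_match: float = 0.0
    match_pairs: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 2))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for f in (self.freq_locus1, self.freq_locus2):
            if not 0.0 < f < 1.0:
                raise ValueError("allele frequencies must lie in (0, 1)")
        if self.s_match < 0:
            raise ValueError("s_match must be non-negative")


def _hw_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def simulate_epistatic_couples(config: EpistasisConfig) -> np.ndarray:
    """3×3 realized offspring genotype-pair table under fertility selection.

    Couples form at Hardy–Weinberg for each locus independently, and each
    couple's offspring contribution is weighted 1 + s_match·[pair is
    compatible], so the realized offspring genotype-pair distribution is
    the weighted product distribution; the table is one multinomial draw of
    ``n_couples`` pairs from it.  s_match = 0 gives exact independence.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.outer(_hw_probs(config.freq_locus1), _hw_probs(config.freq_locus2))
    weight = np.ones((3, 3))
    for a, b in config.match_pairs:
        weight[a, b] += config.s_match
    probs = probs * weight
    probs /= probs.sum()
    draw = rng.multinomial(config.n_couples, probs.ravel())
    return draw.reshape(3, 3)


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(hapset: PhasedHaplotypeSet, path: str) -> None:
    """Write a PhasedHaplotypeSet as VCF 4.2 with phased GT fields."""
    contig_len = int(hapset.positions.max()) + 1 if hapset.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hapset.chromosome or 'chr1'},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hapset.samples)
            + "\n"
        )
        chrom = hapset.chromosome or "chr1"
        for j in range(hapset.n_sites):
            gts = "\t".join(
                f"{hapset.haplotype_matrix[2 * i, j]}|{hapset.haplotype_matrix[2 * i + 1, j]}"
                for i in range(hapset.n_samples)
            )
            fh.write(
                f"{chrom}\t{hapset.positions[j]}\t.\t{hapset.ref_allele[j]}\t"
                f"{hapset.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
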