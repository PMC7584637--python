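"""Seeded generators emulating the statistical structure of the analysis inputs.

Three simulators, all pure functions of (config, seed) via numpy's PCG64:

* :func:`simulate_panel` — discrete-generation forward Wright-Fisher
  evolution of N haploid genomes with infinite-sites mutation, single
  crossover recombination and an optional positively selected focal allele
  (a selective sweep), emitting a sampled :class:`~gnselect.snp_matrix.SnpMatrix`;
* :func:`simulate_codon_pair` — a coding-sequence pair diverged under the
  single-omega codon model used by the dN/dS estimators;
* :func:`simulate_mk_table` — Poisson polymorphism/divergence counts with a
  specified adaptive fraction and optional weakly deleterious rare load.

Scales are deliberately small (N <= ~500, L <= ~200 kb, rates scaled up) so
that runs finish in seconds; this is a scaled model, not a literal plant
demography.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dnds import (
    CodonAlignment,
    SENSE_CODONS,
    _transition_probs,
    build_rate_matrix,
    equal_codon_frequencies,
    _validate_freqs,
)
from .exceptions import GnselectError, SimulationError
from .mk_tests import DivergenceCounts, PolymorphismTable
from .snp_matrix import SnpMatrix

__all__ = [
    "SweepSimConfig", "MkSimConfig", "simulate_panel",
    "simulate_paired_panels", "simulate_codon_pair", "simulate_mk_table",
]


# ---------------------------------------------------------------------- #
# forward Wright-Fisher sweep / neutral panel

@dataclass
class SweepSimConfig:
    pop_size: int = 100            # haploid genomes
    chrom_length: int = 100_000    # bp
    mu: float = 1e-6               # per site per generation
    rec: float = 2e-6              # per bp per generation (single crossover)
    s: float = 0.0                 # focal-allele selection coefficient
    focal_pos: int = 50_000
    n_sample: int = 40
    burn_in: int | None = None     # default 10 * pop_size generations
    post_fix_gens: int | None = None  # default 0.1 * pop_size
    sample_focal_freq: float | None = None  # sample mid-sweep at this freq
    extra_neutral_gens: int = 0    # run-on after burn-in when s == 0
    max_restarts: int = 200
    seed: int = 0
    chrom_name: str = "1"

    def __post_init__(self):
        if self.pop_size < 2:
            raise GnselectError("pop_size must be >= 2")
        if self.s < 0 or self.mu < 0 or self.rec < 0:
            raise GnselectError("s, mu and rec must be nonnegative")
        if not 0 <= self.focal_pos < self.chrom_length:
            raise GnselectError("focal_pos outside [0, chrom_length)")
        if self.n_sample > self.pop_size:
            raise GnselectError(
                f"n_sample {self.n_sample} > pop_size {self.pop_size}")
        if self.burn_in is None:
            self.burn_in = 10 * self.pop_size
        if self.post_fix_gens is None:
            self.post_fix_gens = max(1, int(0.1 * self.pop_size))
        if self.sample_focal_freq is not None and not \
                0.0 < self.sample_focal_freq <= 1.0:
            raise GnselectError("sample_focal_freq must lie in (0, 1]")


class _Population:
    """Haplotypes as a boolean (N, n_sites) matrix over segregating sites."""

    def __init__(self, n: int, length: int, rng: np.random.Generator):
        self.n = n
        self.length = length
        self.rng = rng
        self.geno = np.zeros((n, 0), dtype=bool)
        self.positions = np.zeros(0, dtype=np.int64)
        self.focal_col: int | None = None

    def copy(self):
        other = _Population(self.n, self.length, self.rng)
        other.geno = self.geno.copy()
        other.positions = self.positions.copy()
        other.focal_col = self.focal_col
        return other

    def add_mutations(self, mu: float):
        lam = self.n * mu * self.length
        k = self.rng.poisson(lam)
        if k == 0:
            return
        existing = set(self.positions.tolist())
        new_pos = []
        while len(new_pos) < k:
            p = int(self.rng.integers(0, self.length))
            if p not in existing:
                existing.add(p)
                new_pos.append(p)
        cols = np.zeros((self.n, k), dtype=bool)
        carriers = self.rng.integers(0, self.n, size=k)
        cols[carriers, np.arange(k)] = True
        self.geno = np.concatenate([self.geno, cols], axis=1)
        self.positions = np.concatenate(
            [self.positions, np.asarray(new_pos, dtype=np.int64)])

    def add_focal(self, pos: int):
        clash = self.positions == pos
        if clash.any():  # infinite-sites: evict any standing variant there
            self.geno = self.geno[:, ~clash]
            self.positions = self.positions[~clash]
        col = np.zeros((self.n, 1), dtype=bool)
        col[int(self.rng.integers(0, self.n)), 0] = True
        self.geno = np.concatenate([self.geno, col], axis=1)
        self.positions = np.concatenate(
            [self.positions, np.asarray([pos], dtype=np.int64)])
        self.focal_col = self.geno.shape[1] - 1

    def focal_count(self) -> int:
        if self.focal_col is None:
            return 0
        return int(self.geno[:, self.focal_col].sum())

    def reproduce(self, s: float, rec: float):
        n = self.n
        if s > 0 and self.focal_col is not None:
            w = 1.0 + s * self.geno[:, self.focal_col]
            prob = w / w.sum()
            p1 = self.rng.choice(n, size=n, p=prob)
            p2 = self.rng.choice(n, size=n, p=prob)
        else:
            p1 = self.rng.integers(0, n, size=n)
            p2 = self.rng.integers(0, n, size=n)
        cp = np.full(n, self.length, dtype=np.int64)  # cp = L: pure p1 copy
        recomb = self.rng.random(n) < min(1.0, rec * self.length)
        cp[recomb] = self.rng.integers(0, self.length, size=int(recomb.sum()))
        left = self.positions[None, :] < cp[:, None]
        self.geno = np.where(left, self.geno[p1], self.geno[p2])

    def prune(self):
        counts = self.geno.sum(axis=0)
        seg = (counts > 0) & (counts < self.n)
        if self.focal_col is not None:
            keep_focal = np.zeros_like(seg)
            keep_focal[self.focal_col] = True
            seg = seg | keep_focal
        if not seg.all():
            if self.focal_col is not None:
                self.focal_col = int(seg[:self.focal_col].sum())
            self.geno = self.geno[:, seg]
            self.positions = self.positions[seg]

    def step(self, s: float, mu: float, rec: float):
        self.reproduce(s, rec)
        self.add_mutations(mu)
        self.prune()


def _run_sweep(pop: _Population, cfg: SweepSimConfig, rng):
    """Introduce the focal allele and run until the sampling target.

    Restarts from the supplied (post-burn-in) population on loss.  Returns
    (population, trajectory, fixation_generation).
    """
    target = (cfg.pop_size if cfg.sample_focal_freq is None
              else max(1, int(np.ceil(cfg.sample_focal_freq
                                      * cfg.pop_size))))
    base = pop
    fixation_gen = None
    trajectory: list = []
    for attempt in range(cfg.max_restarts):
        pop = base.copy()
        pop.add_focal(cfg.focal_pos)
        trajectory = [pop.focal_count()]
        gen = 0
        while True:
            pop.step(cfg.s, cfg.mu, cfg.rec)
            gen += 1
            c = pop.focal_count()
            trajectory.append(c)
            if c == 0:
                break  # lost: restart from the post-burn-in state
            if c >= target:
                if c == cfg.pop_size:
                    fixation_gen = gen
                return pop, trajectory, fixation_gen
    raise SimulationError(
        f"focal allele did not reach the sampling target within "
        f"{cfg.max_restarts} restarts")


def _sample_matrix(pop: _Population, cfg: SweepSimConfig, rng) -> SnpMatrix:
    sample_rows = rng.choice(cfg.pop_size, size=cfg.n_sample, replace=False)
    geno = pop.geno[sample_rows]
    counts = geno.sum(axis=0)
    seg = (counts > 0) & (counts < cfg.n_sample)
    geno = geno[:, seg]
    positions = pop.positions[seg]
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    geno = geno[:, order]
    return SnpMatrix(
        chrom=np.full(len(positions), cfg.chrom_name, dtype=object),
        pos=positions + 1,  # 1-based
        ref_allele=np.full(len(positions), "A", dtype=object),
        alt_allele=np.full(len(positions), "T", dtype=object),
        genotypes=geno.T.astype(np.int8),
        sample_ids=[f"acc{i:03d}" for i in range(cfg.n_sample)],
    )


def simulate_panel(cfg: SweepSimConfig):
    """Run the forward simulation and sample a SNP panel.

    Returns (SnpMatrix, truth) where truth records the scenario, the focal
    allele trajectory during the sweep phase and the fixation generation
    (None for neutral runs).  Deterministic for identical (cfg, seed).
    """
    rng = np.random.default_rng(np.random.PCG64(cfg.seed))
    pop = _Population(cfg.pop_size, cfg.chrom_length, rng)
    for _ in range(cfg.burn_in):
        pop.step(0.0, cfg.mu, cfg.rec)

    trajectory: list = []
    fixation_gen = None
    if cfg.s > 0:
        pop, trajectory, fixation_gen = _run_sweep(pop, cfg, rng)
        if cfg.sample_focal_freq is None:
            for _ in range(cfg.post_fix_gens):
                pop.step(cfg.s, cfg.mu, cfg.rec)
    else:
        for _ in range(cfg.extra_neutral_gens):
            pop.step(0.0, cfg.mu, cfg.rec)

    m = _sample_matrix(pop, cfg, rng)
    truth = {
        "config": asdict(cfg),
        "fixation_generation": fixation_gen,
        "focal_trajectory": trajectory,
        "n_segregating_sampled": m.n_sites,
    }
    return m, truth


def simulate_paired_panels(cfg: SweepSimConfig):
    """Matched neutral/sweep panel pair sharing one burn-in population.

    The neutral panel is sampled at the end of the burn-in; the sweep then
    continues from the very same population state (cfg.s must be > 0).
    Returns (neutral_matrix, sweep_matrix, truth).  Deterministic per
    (cfg, seed).
    """
    if cfg.s <= 0:
        raise GnselectError("simulate_paired_panels requires s > 0")
    rng = np.random.default_rng(np.random.PCG64(cfg.seed))
    pop = _Population(cfg.pop_size, cfg.chrom_length, rng)
    for _ in range(cfg.burn_in):
        pop.step(0.0, cfg.mu, cfg.rec)
    neutral = _sample_matrix(pop.copy(), cfg, rng)
    pop, trajectory, fixation_gen = _run_sweep(pop, cfg, rng)
    if cfg.sample_focal_freq is None:
        for _ in range(cfg.post_fix_gens):
            pop.step(cfg.s, cfg.mu, cfg.rec)
    sweep = _sample_matrix(pop, cfg, rng)
    truth = {
        "config": asdict(cfg),
        "fixation_generation": fixation_gen,
        "focal_trajectory": trajectory,
    }
    return neutral, sweep, truth


# ---------------------------------------------------------------------- #
# codon-pair divergence under the single-omega model

def simulate_codon_pair(n_codons: int, t: float, kappa: float, omega: float,
                        codon_freqs=None, seed: int = 0) -> CodonAlignment:
    """Diverge two sequences from a common ancestor for t/2 each.

    Ancestor codons are drawn from ``codon_freqs`` (uniform over the 61
    sense codons by default); both lineages evolve under the same scaled
    rate matrix as the likelihood calculation.  Deterministic per seed.
    """
    if n_codons < 1:
        raise GnselectError("n_codons must be >= 1")
    if t < 0:
        raise GnselectError("t must be >= 0")
    pi = (_validate_freqs(codon_freqs) if codon_freqs is not None
          else equal_codon_frequencies())
    rng = np.random.default_rng(np.random.PCG64(seed))
    anc = rng.choice(len(SENSE_CODONS), size=n_codons, p=pi)
    if t == 0:
        a = b = anc
    else:
        q = build_rate_matrix(kappa, omega, pi)
        p = _transition_probs(q, pi, t / 2.0)
        p = p / p.sum(axis=1, keepdims=True)
        a = np.empty(n_codons, dtype=np.int64)
        b = np.empty(n_codons, dtype=np.int64)
        for i in np.unique(anc):  # one vectorised draw per ancestral codon
            idx = np.flatnonzero(anc == i)
            a[idx] = rng.choice(len(SENSE_CODONS), size=len(idx), p=p[i])
            b[idx] = rng.choice(len(SENSE_CODONS), size=len(idx), p=p[i])
    seq_a = "".join(SENSE_CODONS[i] for i in a)
    seq_b = "".join(SENSE_CODONS[i] for i in b)
    return CodonAlignment(seq_a, seq_b, id_a=f"sim{seed}_a",
                          id_b=f"sim{seed}_b")


# ---------------------------------------------------------------------- #
# polymorphism / divergence count tables

@dataclass
class MkSimConfig:
    true_alpha: float = 0.0
    ln_sites: float = 1000.0        # nonsynonymous site total
    ls_sites: float = 500.0         # synonymous site total
    theta: float = 0.05             # per-site polymorphism intensity
    lam: float = 0.1                # per-site divergence intensity
    deleterious_fraction: float = 0.0  # extra rare nonsyn load, relative
    del_freq_skew: float = 20.0     # Beta(1, skew) frequencies for the load
    sample_n: int = 100             # chromosomes behind the frequency lattice
    seed: int = 0

    def __post_init__(self):
        if self.true_alpha >= 1.0:
            raise GnselectError("true_alpha must be < 1")
        if self.theta <= 0 or self.lam <= 0:
            raise GnselectError("intensities must be positive")
        if self.deleterious_fraction < 0:
            raise GnselectError("deleterious_fraction must be >= 0")


def _neutral_frequencies(rng, k, n):
    """Frequencies i/n with P(i) proportional to 1/i (neutral SFS shape)."""
    i = np.arange(1, n)
    p = (1.0 / i) / (1.0 / i).sum()
    return rng.choice(i, size=k, p=p) / n


def simulate_mk_table(cfg: MkSimConfig):
    """Draw a (PolymorphismTable, DivergenceCounts, truth) triple.

    Neutral construction: Pn, Ps, Ds Poisson with class-proportional
    intensities; Dn has a neutral part plus an adaptive part sized so the
    expected standard-MKT alpha equals ``true_alpha``.  The optional weakly
    deleterious load adds nonsynonymous polymorphisms with rare-skewed
    Beta(1, del_freq_skew) frequencies.
    """
    rng = np.random.default_rng(np.random.PCG64(cfg.seed))
    ps = rng.poisson(cfg.theta * cfg.ls_sites)
    pn_neutral = rng.poisson(cfg.theta * cfg.ln_sites)
    ds = rng.poisson(cfg.lam * cfg.ls_sites)
    dn_neutral = rng.poisson(cfg.lam * cfg.ln_sites)
    adaptive_rate = cfg.lam * cfg.ln_sites * cfg.true_alpha / (1 - cfg.true_alpha)
    dn_adaptive = rng.poisson(adaptive_rate) if adaptive_rate > 0 else 0
    n_del = (rng.poisson(cfg.deleterious_fraction * cfg.theta * cfg.ln_sites)
             if cfg.deleterious_fraction > 0 else 0)

    n = cfg.sample_n
    lattice = lambda f: np.clip(f, 1.0 / n, (n - 1.0) / n)
    rows = []
    freqs = _neutral_frequencies(rng, ps, n)
    rows += [("s", f) for f in freqs]
    freqs = _neutral_frequencies(rng, pn_neutral, n)
    rows += [("n", f) for f in freqs]
    if n_del:
        freqs = lattice(rng.beta(1.0, cfg.del_freq_skew, size=n_del))
        rows += [("n", f) for f in freqs]
    df = pd.DataFrame(
        {"site_id": [f"site{i:05d}" for i in range(len(rows))],
         "cls": ["synonymous" if c == "s" else "nonsynonymous"
                 for c, _ in rows],
         "frequency": [f for _, f in rows]})
    poly = PolymorphismTable(df, frequency_kind="derived")
    div = DivergenceCounts(dn=int(dn_neutral + dn_adaptive), ds=int(ds),
                           ln_sites=cfg.ln_sites, ls_sites=cfg.ls_sites)
    truth = {
        "config": asdict(cfg),
        "pn_neutral": int(pn_neutral), "pn_deleterious": int(n_del),
        "ps": int(ps), "dn_neutral": int(dn_neutral),
        "dn_adaptive": int(dn_adaptive), "ds": int(ds),
        "realized_alpha": (dn_adaptive / (dn_neutral + dn_adaptive)
                           if dn_neutral + dn_adaptive else float("nan")),
    }
    return poly, div, truth
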