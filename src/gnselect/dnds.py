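"""Pairwise dN/dS estimation and the likelihood-ratio test against omega=1.

Two estimators are provided for a pair of aligned coding sequences:

* :func:`ng86` — Nei-Gojobori counting with Jukes-Cantor correction:
  synonymous site fractions averaged over the two sequences, observed
  differences resolved by averaging over all mutational pathways (pathways
  through stop codons excluded, with renormalisation).
* :func:`fit_pairwise_ml` / :func:`lrt_omega` — a single-omega Goldman-Yang
  codon model fit by maximum likelihood over (t, kappa, omega), with the
  nested fit at omega=1 supplying a chi-square(1) likelihood-ratio test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg, optimize, stats
from Bio.Data import CodonTable

from .exceptions import (
    AlignmentError,
    ConvergenceError,
    FrameError,
    GnselectError,
    InvalidCdsError,
)

__all__ = [
    "CodonAlignment", "DnDsResult", "prepare_codon_alignment", "ng86",
    "gy94_loglik", "fit_pairwise_ml", "lrt_omega", "f3x4_frequencies",
    "equal_codon_frequencies", "build_rate_matrix", "SENSE_CODONS",
    "CODON_INDEX",
]

_NT = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
#: The 61 sense codons of the universal code, in TCAG order.
SENSE_CODONS: tuple = tuple(
    c for c in ("".join(p) for p in itertools.product(_NT, repeat=3))
    if c not in STOP_CODONS)
CODON_INDEX: dict = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(x: str, y: str) -> bool:
    return (x, y) in _TRANSITIONS


def _single_change_structure():
    """Index arrays for all sense-codon pairs one nucleotide apart."""
    src, dst, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            src.append(i)
            dst.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            syn.append(_AA[ci] == _AA[cj])
    return (np.asarray(src), np.asarray(dst),
            np.asarray(ts, dtype=bool), np.asarray(syn, dtype=bool))


_SRC, _DST, _TS, _SYN = _single_change_structure()


# ---------------------------------------------------------------------- #
# data types

@dataclass
class CodonAlignment:
    """A cleaned pair of equal-length, gap-free coding sequences."""

    seq_a: str
    seq_b: str
    id_a: str = "seq_a"
    id_b: str = "seq_b"
    n_dropped_codons: int = 0

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError("paired sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise FrameError(f"length {len(self.seq_a)} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for k in range(0, len(self.seq_a), 3):
            yield self.seq_a[k:k + 3], self.seq_b[k:k + 3]


@dataclass
class DnDsResult:
    method: str                 # "NG86" | "ML"
    dN: float
    dS: float
    omega: float
    logL_free: float | None = None
    logL_null: float | None = None
    lrt_stat: float | None = None
    p_value: float | None = None
    flags: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        """Passes the p < 0.001 plotting rule for LRT results."""
        return self.p_value is not None and self.p_value < 0.001


# ---------------------------------------------------------------------- #
# alignment preparation

_VALID = frozenset("ACGT")


def prepare_codon_alignment(cds_a, cds_b, id_a: str | None = None,
                            id_b: str | None = None,
                            min_codons: int = 0) -> CodonAlignment:
    """Validate and clean a pre-aligned CDS pair into a CodonAlignment.

    Accepts strings or Bio.SeqRecord objects of equal length.  Codon columns
    containing a gap or ambiguity character in either sequence are dropped
    from both; a terminal stop column is stripped; an internal stop after
    cleaning raises :class:`InvalidCdsError`.
    """
    a, ia = _coerce_seq(cds_a, id_a, "seq_a")
    b, ib = _coerce_seq(cds_b, id_b, "seq_b")
    if not a or not b:
        raise AlignmentError("empty sequence")
    if len(a) != len(b):
        raise AlignmentError(
            f"sequences must be pre-aligned to equal length "
            f"({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise FrameError(f"aligned length {len(a)} not divisible by 3")
    cols_a, cols_b, dropped = [], [], 0
    for k in range(0, len(a), 3):
        ca, cb = a[k:k + 3], b[k:k + 3]
        if set(ca) <= _VALID and set(cb) <= _VALID:
            cols_a.append(ca)
            cols_b.append(cb)
        else:
            dropped += 1
    if cols_a and (cols_a[-1] in STOP_CODONS or cols_b[-1] in STOP_CODONS):
        cols_a.pop()
        cols_b.pop()
    for ca, cb in zip(cols_a, cols_b):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise InvalidCdsError(
                f"internal stop codon in alignment ({ca}/{cb})")
    if len(cols_a) < max(min_codons, 1):
        raise AlignmentError(
            f"only {len(cols_a)} codons remain after cleaning "
            f"(minimum {max(min_codons, 1)})")
    return CodonAlignment("".join(cols_a), "".join(cols_b), id_a=ia, id_b=ib,
                          n_dropped_codons=dropped)


def _coerce_seq(obj, explicit_id, default_id):
    if hasattr(obj, "seq"):  # Bio.SeqRecord
        return (str(obj.seq).upper().replace("U", "T"),
                explicit_id or obj.id or default_id)
    return str(obj).upper().replace("U", "T"), explicit_id or default_id


# ---------------------------------------------------------------------- #
# NG86 counting estimator

@lru_cache(maxsize=4096)
def _syn_site_fraction(codon: str) -> float:
    """Fraction of the 9 single-nucleotide changes that are synonymous.

    Convention: changes producing a stop codon count as nonsynonymous, so
    every codon contributes exactly 3 sites (N + S = 3 per codon).
    """
    s = 0.0
    for k in range(3):
        for nt in _NT:
            if nt == codon[k]:
                continue
            alt = codon[:k] + nt + codon[k + 1:]
            if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=65536)
def _pathway_differences(ca: str, cb: str):
    """Average (nonsyn, syn) step counts over mutational pathways ca -> cb.

    Pathways passing through a stop codon are excluded and the average is
    renormalised over the remainder; if every pathway is excluded, all are
    used (degenerate corner of the convention).
    """
    diff = [k for k in range(3) if ca[k] != cb[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        ok = True
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(_AA[cur] == _AA[nxt])
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # fall back: count through-stop steps as nonsynonymous
        for order in itertools.permutations(diff):
            cur = ca
            steps = []
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1:]
                syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                       and _AA.get(cur) == _AA.get(nxt))
                steps.append(syn)
                cur = nxt
            paths.append(steps)
    nd = np.mean([sum(1 for s in p if not s) for p in paths])
    sd = np.mean([sum(1 for s in p if s) for p in paths])
    return float(nd), float(sd)


def _jukes_cantor(p: float):
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86(aln: CodonAlignment) -> DnDsResult:
    """Nei-Gojobori counting dN/dS with Jukes-Cantor correction."""
    if aln.n_codons < 1:
        raise GnselectError("empty alignment")
    s_sites = 0.0
    nd = sd = 0.0
    for ca, cb in aln.codons():
        s_sites += 0.5 * (_syn_site_fraction(ca) + _syn_site_fraction(cb))
        d_n, d_s = _pathway_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = 3.0 * aln.n_codons - s_sites
    flags: list = []
    p_n = nd / n_sites if n_sites > 0 else 0.0
    p_s = sd / s_sites if s_sites > 0 else 0.0
    d_n_hat, sat_n = _jukes_cantor(p_n)
    d_s_hat, sat_s = _jukes_cantor(p_s)
    if sat_n or sat_s:
        flags.append("saturated")
    if d_s_hat == 0.0 or np.isnan(d_s_hat):
        omega = float("nan")
        if not (sat_n or sat_s):
            flags.append("undefined_omega")
    else:
        omega = d_n_hat / d_s_hat
        if np.isnan(omega):
            flags.append("undefined_omega")
    return DnDsResult(
        method="NG86", dN=d_n_hat, dS=d_s_hat, omega=omega, flags=flags,
        extras={"N": n_sites, "S": s_sites, "Nd": nd, "Sd": sd,
                "pN": p_n, "pS": p_s})


# ---------------------------------------------------------------------- #
# GY94 single-omega codon model

def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-8) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts."""
    counts = np.zeros((3, 4))
    for seq in (aln.seq_a, aln.seq_b):
        for k, nt in enumerate(seq):
            counts[k % 3, _NT.index(nt)] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(len(SENSE_CODONS))
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = np.prod([probs[k, _NT.index(codon[k])] for k in range(3)])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def equal_codon_frequencies() -> np.ndarray:
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


def _validate_freqs(codon_freqs) -> np.ndarray:
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (len(SENSE_CODONS),):
        raise GnselectError(
            f"codon_freqs must have length {len(SENSE_CODONS)}")
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise GnselectError("codon_freqs must be positive and sum to 1")
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, codon_freqs) -> np.ndarray:
    """Scaled GY94 rate matrix: mean substitution rate 1 per codon site."""
    if kappa <= 0 or omega <= 0:
        raise GnselectError("kappa and omega must be positive")
    pi = _validate_freqs(codon_freqs)
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    rate = pi[_DST] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    q[_SRC, _DST] = rate
    q[np.diag_indices(n)] = -q.sum(axis=1)
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise GnselectError("degenerate rate matrix")
    return q / scale


def _transition_probs(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via eigendecomposition of the symmetrised generator."""
    sq = np.sqrt(pi)
    b = (sq[:, None] * q) / sq[None, :]
    w, u = linalg.eigh((b + b.T) / 2.0)
    p = (u * np.exp(w * t)) @ u.T
    p = (p / sq[:, None]) * sq[None, :]
    return np.clip(p, 1e-300, None)


def _pair_counts(aln: CodonAlignment) -> np.ndarray:
    n = len(SENSE_CODONS)
    counts = np.zeros((n, n))
    for ca, cb in aln.codons():
        counts[CODON_INDEX[ca], CODON_INDEX[cb]] += 1
    return counts


def gy94_loglik(aln: CodonAlignment, t: float, kappa: float, omega: float,
                codon_freqs) -> float:
    """Log-likelihood of the pair under the single-omega codon model.

    l = sum over codon sites of log(pi_i * P_ij(t)), with the rate matrix
    scaled so the expected number of substitutions per codon site equals t.
    Time-reversible, hence symmetric in the two sequences.
    """
    if t < 0:
        raise GnselectError("t must be >= 0")
    pi = _validate_freqs(codon_freqs)
    counts = _pair_counts(aln)
    if t == 0:
        # limit: P -> I; identical columns contribute log pi, others -inf
        if np.any(counts * (1 - np.eye(len(pi)))):
            return -np.inf
        return float((np.diag(counts) * np.log(pi)).sum())
    q = build_rate_matrix(kappa, omega, pi)
    p = _transition_probs(q, pi, t)
    return float((counts * (np.log(pi)[:, None] + np.log(p))).sum())


@dataclass
class MlFit:
    t: float
    kappa: float
    omega: float
    logL: float
    converged: bool
    boundary: bool
    fixed_omega: float | None = None


_BOUNDS_T = (1e-6, 50.0)
_BOUNDS_K = (1e-4, 100.0)
_BOUNDS_W = (1e-4, 100.0)


def fit_pairwise_ml(aln: CodonAlignment, fix_omega: float | None = None,
                    codon_freqs=None, n_starts: int = 3,
                    extra_starts=()) -> MlFit:
    """Maximise the GY94 pair likelihood over (t, kappa[, omega]).

    Optimisation runs on log-transformed parameters with L-BFGS-B and
    multistart; ``fix_omega`` pins omega for the null fit.
    """
    pi = (_validate_freqs(codon_freqs) if codon_freqs is not None
          else f3x4_frequencies(aln))
    counts = _pair_counts(aln)
    log_pi = np.log(pi)
    free_omega = fix_omega is None

    def negll(logparams):
        t = np.exp(logparams[0])
        kappa = np.exp(logparams[1])
        omega = np.exp(logparams[2]) if free_omega else fix_omega
        q = build_rate_matrix(kappa, omega, pi)
        p = _transition_probs(q, pi, t)
        return -float((counts * (log_pi[:, None] + np.log(p))).sum())

    ndiff = sum(1 for ca, cb in aln.codons() if ca != cb)
    pdiff = ndiff / max(aln.n_codons, 1)
    t0 = max(5e-3, -np.log(max(1e-6, 1.0 - pdiff)) * 3.0)
    starts = [(t0, 2.0, 0.4), (t0 * 3, 1.0, 1.0), (max(t0 / 3, 2e-3), 4.0, 0.1)]
    starts = starts[:max(1, n_starts)] + list(extra_starts)

    lb = np.log([_BOUNDS_T[0], _BOUNDS_K[0], _BOUNDS_W[0]])
    ub = np.log([_BOUNDS_T[1], _BOUNDS_K[1], _BOUNDS_W[1]])
    best = None
    any_ok = False
    for t_s, k_s, w_s in starts:
        x0 = np.log([np.clip(t_s, *_BOUNDS_T), np.clip(k_s, *_BOUNDS_K),
                     np.clip(w_s, *_BOUNDS_W)])
        nfree = 3 if free_omega else 2
        fun = lambda x: negll(np.concatenate([x, x0[nfree:]]))
        res = optimize.minimize(
            fun, x0[:nfree], method="L-BFGS-B",
            bounds=list(zip(lb[:nfree], ub[:nfree])),
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500})
        if not res.success:
            # line-search failures near the optimum are common with numeric
            # gradients; polish with a derivative-free pass
            polish = optimize.minimize(
                fun, np.clip(res.x, lb[:nfree], ub[:nfree]),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
            if polish.fun <= res.fun:
                res = polish
        any_ok = any_ok or res.success
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (res.fun, np.clip(res.x, lb[:nfree], ub[:nfree]),
                    res.success)
    if best is None or not np.isfinite(best[0]):
        raise ConvergenceError("all optimisation starts failed")
    if not any_ok:
        raise ConvergenceError(
            f"optimiser did not converge after {len(starts)} starts")
    fun, x, _ = best
    t_hat = float(np.exp(x[0]))
    kappa_hat = float(np.exp(x[1]))
    omega_hat = float(np.exp(x[2])) if free_omega else float(fix_omega)
    boundary = t_hat <= _BOUNDS_T[0] * 2
    return MlFit(t=t_hat, kappa=kappa_hat, omega=omega_hat, logL=-float(fun),
                 converged=True, boundary=boundary, fixed_omega=fix_omega)


def _ml_dn_ds(fit: MlFit, pi: np.ndarray):
    """Decompose t into dN and dS using model-based site proportions."""
    q = build_rate_matrix(fit.kappa, fit.omega, pi)
    flux = pi[_SRC] * q[_SRC, _DST]
    rho_s = flux[_SYN].sum() / flux.sum()
    q1 = build_rate_matrix(fit.kappa, 1.0, pi)
    flux1 = pi[_SRC] * q1[_SRC, _DST]
    s_prop = flux1[_SYN].sum() / flux1.sum()  # mutational opportunity
    ds = fit.t * rho_s / (3.0 * s_prop) if s_prop > 0 else float("nan")
    dn = fit.t * (1 - rho_s) / (3.0 * (1 - s_prop)) if s_prop < 1 else float("nan")
    return dn, ds


def lrt_omega(aln: CodonAlignment, codon_freqs=None,
              n_starts: int = 3) -> DnDsResult:
    """Likelihood-ratio test of the free-omega fit against omega = 1.

    lrt_stat = 2 (l_free - l_null), clamped at 0; p from the chi-square(1)
    upper tail.  The result records the p < 0.001 significance convention.
    """
    pi = (_validate_freqs(codon_freqs) if codon_freqs is not None
          else f3x4_frequencies(aln))
    null = fit_pairwise_ml(aln, fix_omega=1.0, codon_freqs=pi,
                           n_starts=n_starts)
    free = fit_pairwise_ml(aln, codon_freqs=pi, n_starts=n_starts,
                           extra_starts=[(null.t, null.kappa, 1.0)])
    stat = max(0.0, 2.0 * (free.logL - null.logL))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    dn, ds = _ml_dn_ds(free, pi)
    flags = []
    if free.boundary:
        flags.append("boundary")
    return DnDsResult(
        method="ML", dN=dn, dS=ds, omega=free.omega,
        logL_free=free.logL, logL_null=null.logL, lrt_stat=stat, p_value=p,
        flags=flags,
        extras={"t": free.t, "kappa": free.kappa, "t_null": null.t,
                "kappa_null": null.kappa})
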