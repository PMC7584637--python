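"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's own implementations: naive loops,
explicit enumeration and scipy.linalg.expm, so that agreement is evidence
rather than tautology.
"""

import itertools

import numpy as np

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def naive_r_squared(a, b):
    """Squared Pearson correlation via the textbook formula, plain loops."""
    a = [int(x) for x in a]
    b = [int(x) for x in b]
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov * cov / (va * vb)


def ng86_oracle(seq_a, seq_b):
    """Enumerate NG86 site fractions and pathway-averaged differences.

    Returns (N, S, Nd, Sd).  Stop-producing single changes count as
    nonsynonymous sites; pathways through stops are dropped with
    renormalisation.
    """
    def syn_sites(codon):
        s = 0.0
        for k in range(3):
            for nt in "ACGT":
                if nt == codon[k]:
                    continue
                alt = codon[:k] + nt + codon[k + 1:]
                if GENETIC_CODE[alt] != "*" and \
                        GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                    s += 1 / 3
        return s

    def path_diffs(ca, cb):
        positions = [k for k in range(3) if ca[k] != cb[k]]
        if not positions:
            return 0.0, 0.0
        nd_list, sd_list = [], []
        for order in itertools.permutations(positions):
            cur, nd, sd, ok = ca, 0, 0, True
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1:]
                if GENETIC_CODE[nxt] == "*":
                    ok = False
                    break
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                nd_list.append(nd)
                sd_list.append(sd)
        if not nd_list:
            return float(len(positions)), 0.0
        return float(np.mean(nd_list)), float(np.mean(sd_list))

    s_total = nd_total = sd_total = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k:k + 3], seq_b[k:k + 3]
        s_total += (syn_sites(ca) + syn_sites(cb)) / 2
        nd, sd = path_diffs(ca, cb)
        nd_total += nd
        sd_total += sd
    n_total = len(seq_a) - s_total
    return n_total, s_total, nd_total, sd_total


def gy94_loglik_expm_oracle(seq_a, seq_b, t, kappa, omega, codon_freqs):
    """Pair log-likelihood with its own Q construction and scipy expm."""
    from scipy.linalg import expm

    sense = [c for c in ("".join(p)
                         for p in itertools.product("TCAG", repeat=3))
             if GENETIC_CODE[c] != "*"]
    index = {c: i for i, c in enumerate(sense)}
    pi = np.asarray(codon_freqs, dtype=float)
    n = len(sense)
    q = np.zeros((n, n))
    transitions = {frozenset("AG"), frozenset("CT")}
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = pi[j]
            if frozenset((ci[k], cj[k])) in transitions:
                rate *= kappa
            if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(pi * np.diag(q)).sum()
    p = expm(q * t)
    ll = 0.0
    for k in range(0, len(seq_a), 3):
        i, j = index[seq_a[k:k + 3]], index[seq_b[k:k + 3]]
        ll += np.log(pi[i] * p[i, j])
    return ll
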