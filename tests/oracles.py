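"""Independent brute-force oracles used by the test suite.

Deliberately naive: explicit Python loops, no code shared with the package,
so that agreement with the library implementations is an actual check.
"""

from dtikit.io import CANONICAL_AA


def naive_apaac(sequence, lam, weight, h1, h2):
    """APAAC by explicit loops over residue pairs."""
    n = len(sequence)
    taus = []
    for j in range(1, lam + 1):
        s1 = 0.0
        s2 = 0.0
        for k in range(n - j):
            s1 += h1[sequence[k]] * h1[sequence[k + j]]
            s2 += h2[sequence[k]] * h2[sequence[k + j]]
        taus.append(s1 / (n - j))
        taus.append(s2 / (n - j))
    freqs = [sequence.count(a) / n for a in CANONICAL_AA]
    denom = sum(freqs) + weight * sum(taus)
    return [f / denom for f in freqs] + [weight * t / denom for t in taus]


def pair_counting_auc(labels, scores):
    """AUC as the fraction of concordant positive/negative score pairs.

    O(n^2) comparison of every (positive, negative) pair; ties count half.
    """
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
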