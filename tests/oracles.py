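"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration (never by
calling the implementation under test).
"""

from __future__ import annotations

import numpy as np

from embryoqtl.datatypes import HET, HOM


def brute_trim(bases: str, qualities, min_trim: int = 3) -> str:
    """Enumerate every candidate trim position and apply the scoring rule.

    s_i = sum of Q over A bases after position i minus 3x sum of Q over
    non-A bases after position i, i = 0..len; ties prefer keeping more bases;
    trim only if >= min_trim bases would be removed.
    """
    n = len(bases)
    q = np.asarray(qualities)
    contrib = np.array([q[j] if bases[j] == "A" else -3 * q[j] for j in range(n)])
    best_i, best_s = None, None
    for i in range(n + 1):
        s = int(contrib[i:].sum())  # independent evaluation per candidate position
        if best_s is None or s > best_s or (s == best_s and i > best_i):
            best_i, best_s = i, s
    if n - best_i >= min_trim:
        return bases[:best_i]
    return bases


def _emission_logs(observations, epsilon):
    """n x 2 log-emission matrix for states (het, hom)."""
    le = np.empty((len(observations), 2))
    for i, obs in enumerate(observations):
        if obs == HET:
            le[i] = (np.log(1 - epsilon), np.log(epsilon))
        elif obs == HOM:
            le[i] = (np.log(epsilon), np.log(1 - epsilon))
        else:
            le[i] = (np.log(0.5), np.log(0.5))
    return le


def path_log_prob(observations, path, epsilon, transition) -> float:
    """Joint log probability of a het/hom state path and the observations."""
    le = _emission_logs(observations, epsilon)
    codes = np.array([0 if s == HET else 1 for s in path])
    lp = np.log(0.5) + le[np.arange(len(codes)), codes].sum()
    switches = int((codes[1:] != codes[:-1]).sum())
    lp += switches * np.log(transition) + (len(codes) - 1 - switches) * np.log(1 - transition)
    return float(lp)


def brute_force_best_paths(observations, epsilon, transition):
    """Score all 2^n state paths; return (max log prob, winning paths).

    Vectorised over the 2^n paths so chromosomes of up to ~20 genes stay
    cheap; winners are returned as arrays over {het, hom}.
    """
    n = len(observations)
    k = 2**n
    le = _emission_logs(observations, epsilon)
    idx = np.arange(k, dtype=np.int64)
    score = np.full(k, np.log(0.5))
    prev_bits = None
    log_t, log_s = np.log(transition), np.log(1 - transition)
    for i in range(n):
        bits = (idx >> i) & 1  # 0 = het, 1 = hom at position i
        score += np.where(bits == 0, le[i, 0], le[i, 1])
        if prev_bits is not None:
            score += np.where(bits != prev_bits, log_t, log_s)
        prev_bits = bits
    best = score.max()
    winners = np.nonzero(score >= best - 1e-9)[0]
    paths = []
    for w in winners:
        bits = (w >> np.arange(n)) & 1
        paths.append(np.where(bits == 0, HET, HOM).astype(object))
    return float(best), paths
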