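"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — direct enumeration or textbook
formulas — and shares no code with the package implementation.
"""

from __future__ import annotations

import math


def levenshtein(a: str, b: str) -> int:
    """Plain O(len(a)*len(b)) edit distance, unit costs."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1))
        prev = cur
    return prev[-1]


def _edit_distance(a: str, b: str) -> int:
    try:
        import edlib
    except ImportError:
        return levenshtein(a, b)
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW")["editDistance"]


def brute_force_trim_point(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int = 3
) -> int:
    """Start of the best qualifying 3'-adapter occurrence, or -1.

    Enumerates every (adapter prefix length L, start s, end e) triple:
    full-adapter occurrences may end anywhere, shorter prefixes must run
    to the read's 3' end.  Errors are Levenshtein with budget
    floor(max_error_rate * L).  Preference: larger L, then smaller s.
    Spans with ``|span - L| > budget`` cannot qualify (edit distance is
    at least the length difference) and are skipped.
    """
    n, m = len(seq), len(adapter)
    for L in range(m, min_overlap - 1, -1):
        budget = int(max_error_rate * L)
        prefix = adapter[:L]
        for s in range(n):
            if L == m:
                ends = range(max(s, s + L - budget), min(n, s + L + budget) + 1)
            else:
                ends = [n]
            for e in ends:
                if abs((e - s) - L) > budget:
                    continue
                if _edit_distance(prefix, seq[s:e]) <= budget:
                    return s
    return -1


def brute_force_trim(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int = 3
) -> str:
    s = brute_force_trim_point(seq, adapter, max_error_rate, min_overlap)
    return seq if s < 0 else seq[:s]


def welch_t(a, b) -> tuple[float, float]:
    """Hand-coded Welch two-sample t-test (two-sided), textbook formulas."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def pearson_r(x, y) -> float:
    """Covariance-formula Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def tally_bias_classes(log2_fds, detected_flags, tau) -> dict[str, float]:
    """Brute-force loop counter for bias-class percentages."""
    n = len(log2_fds)
    under = accurate = over = 0
    for fd, det in zip(log2_fds, detected_flags):
        if not det:
            under += 1
        elif fd < -tau:
            under += 1
        elif fd > tau:
            over += 1
        else:
            accurate += 1
    return {
        "under": 100.0 * under / n,
        "accurate": 100.0 * accurate / n,
        "over": 100.0 * over / n,
    }


def tally_class_composition(counts: dict, class_map: dict) -> dict[str, float]:
    """Brute-force read-weighted class percentages."""
    total = sum(counts.values())
    out: dict[str, float] = {}
    for rid, c in counts.items():
        if c == 0:
            continue
        cls = class_map.get(rid, "other")
        out[cls] = out.get(cls, 0.0) + c
    return {k: 100.0 * v / total for k, v in out.items()}
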