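"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a result by direct enumeration or textbook formula,
sharing no code with the package's own implementations.
"""

from __future__ import annotations

import itertools
import math

from cazpipe.io import AnnotationHit

SIGNATURE = {"CAZyme", "TC", "TF", "STP"}


def make_hit(protein="p1", source="HMMER", label="GH16", coverage=0.9,
             identity=0.5, evalue=1e-20, ec=None, domains=()):
    return AnnotationHit(
        protein_id=protein, source=source, label=label, coverage=coverage,
        identity=identity, evalue=evalue, ec=ec, domains=frozenset(domains),
    )


def merge_oracle(assignment: dict[str, str]) -> tuple[str, frozenset] | None:
    """Expected consensus for single-label streams: source -> label.

    Enumerates agreeing source pairs; if any family is supported by >= 2
    sources, reports it with the priority rule (HMMER > eCAMI > DIAMOND).
    With single-label streams at most one family can reach 2 supporters.
    """
    support: dict[str, set] = {}
    for src, label in assignment.items():
        support.setdefault(label, set()).add(src)
    agreed = {fam: srcs for fam, srcs in support.items() if len(srcs) >= 2}
    if not agreed:
        return None
    assert len(agreed) == 1, "unreachable with <=3 single-label streams"
    fam, srcs = next(iter(agreed.items()))
    return fam, frozenset(srcs)


def cgc_windows_oracle(roles: list[str], max_gap: int = 2) -> list[tuple[int, int]]:
    """All maximal valid CGC windows (start, end index) by enumeration.

    A window is valid iff both endpoints are signature genes, every pair of
    consecutive signature genes inside is separated by <= max_gap
    non-signature genes, and it contains >= 1 CAZyme and >= 1 non-CAZyme
    signature gene.  Maximal = not contained in a larger valid window.
    """
    n = len(roles)

    def valid(i: int, j: int) -> bool:
        if roles[i] not in SIGNATURE or roles[j] not in SIGNATURE:
            return False
        sig = [k for k in range(i, j + 1) if roles[k] in SIGNATURE]
        for a, b in zip(sig, sig[1:]):
            if b - a - 1 > max_gap:
                return False
        inside = {roles[k] for k in sig}
        return "CAZyme" in inside and bool(inside & (SIGNATURE - {"CAZyme"}))

    wins = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    return [
        (i, j)
        for (i, j) in wins
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in wins)
    ]


def ranksum_exact(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact Wilcoxon rank-sum: (W = rank sum of a, two-sided exact p).

    Enumerates all C(n1+n2, n1) assignments of the pooled ranks.
    """
    pooled = sorted(a + b)
    # average ranks for ties
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks[pooled[i]] = avg
        i = j
    rank_list = [ranks[v] for v in pooled]
    w_obs = sum(ranks[v] for v in a)
    n1 = len(a)
    ws = [sum(rank_list[i] for i in comb)
          for comb in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    hi = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    return w_obs, min(1.0, 2.0 * min(lo, hi))


def kruskal_h(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H with tie correction, by direct formula."""
    pooled = sorted(x for g in groups for x in g)
    n = len(pooled)
    rank_of = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        rank_of[pooled[i]] = (i + 1 + j) / 2.0
        i = j
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (sum(rank_of[x] for x in g) / len(g)) ** 2 for g in groups
    ) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    denom = 1.0 - ties / (n**3 - n)
    return h / denom if denom > 0 else float("nan")


def bray_curtis(x: list[float], y: list[float]) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def pearson_formula(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def consensus_outcome_probs(label_noise: float, n_families: int) -> dict[str, float]:
    """Closed-form per-protein consensus outcome under the noise model.

    Three independent streams; each reports the true family with
    probability 1 - label_noise, else a uniform wrong family among
    n_families - 1.  Returns P(correct), P(wrong call), P(no call).
    """
    q = 1.0 - label_noise
    m = n_families - 1  # wrong-label alphabet size
    p_correct = q**3 + 3 * q**2 * (1 - q)
    p_wrong = 3 * q * (1 - q) ** 2 / m
    if m >= 2:
        p_all_distinct = (m - 1) * (m - 2) / m**2
    else:
        p_all_distinct = 0.0
    p_wrong += (1 - q) ** 3 * (1 - p_all_distinct)
    return {
        "correct": p_correct,
        "wrong": p_wrong,
        "no_call": 1.0 - p_correct - p_wrong,
    }
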