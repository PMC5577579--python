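"""Independent brute-force oracle for local profile HMM scoring.

Enumerates every local alignment path explicitly (enter at any match
state with no cost, traverse match/insert/delete transitions, exit after
any match state) and accumulates path log-odds. Written against the model
parameter arrays only, with no shared code with the dynamic-programming
implementation it checks.
"""

from __future__ import annotations

import math

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _log2(p: float) -> float:
    return math.log2(p) if p > 0 else float("-inf")


def enumerate_local_paths(model, residues: str) -> tuple[float, float]:
    """Return (best path log-odds, log2 of the summed path odds)."""
    M = model.length
    L = len(residues)
    idx = [AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else -1
           for ch in residues]
    bg = model.background

    def em(node: int, i: int) -> float:
        if idx[i] < 0:
            return 0.0
        return _log2(model.match_emissions[node - 1][idx[i]] / bg[idx[i]])

    def ei(node: int, i: int) -> float:
        if idx[i] < 0:
            return 0.0
        return _log2(model.insert_emissions[node][idx[i]] / bg[idx[i]])

    def lt(node: int, col: int) -> float:
        return _log2(model.transitions[node][col])

    T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

    endpoints: list[float] = []

    def from_match(k: int, i: int, acc: float) -> None:
        endpoints.append(acc)  # every match state is a legal exit
        if k < M and i + 1 < L:
            from_match(k + 1, i + 1, acc + lt(k, T_MM) + em(k + 1, i + 1))
        if 1 <= k < M and i + 1 < L:
            from_insert(k, i + 1, acc + lt(k, T_MI) + ei(k, i + 1))
        if k + 1 <= M and k < M:
            from_delete(k + 1, i, acc + lt(k, T_MD))

    def from_insert(k: int, i: int, acc: float) -> None:
        if k < M and i + 1 < L:
            from_match(k + 1, i + 1, acc + lt(k, T_IM) + em(k + 1, i + 1))
        if i + 1 < L:
            from_insert(k, i + 1, acc + lt(k, T_II) + ei(k, i + 1))

    def from_delete(k: int, i: int, acc: float) -> None:
        if k < M and i + 1 < L:
            from_match(k + 1, i + 1, acc + lt(k, T_DM) + em(k + 1, i + 1))
        if k < M:
            from_delete(k + 1, i, acc + lt(k, T_DD))

    for i in range(L):
        for k in range(1, M + 1):
            from_match(k, i, em(k, i))

    finite = [a for a in endpoints if a > float("-inf")]
    if not finite:
        return float("-inf"), float("-inf")
    best = max(finite)
    total = sum(2.0 ** (a - best) for a in finite)
    return best, best + math.log2(total)
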