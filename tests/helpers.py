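"""Independent oracles used by the test suite.

These re-derive expected results by brute force, deliberately avoiding the
package's own code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from heteropath.expansion import HeterologousPathway


def empty_pathway(target: str) -> HeterologousPathway:
    return HeterologousPathway(target=target, reactions=[], connection_iteration="native")


def vertex_enumeration_max(fm, objective_column: str) -> float:
    """Brute-force LP optimum for max v_j s.t. S v = 0, l <= v <= u.

    Enumerates every candidate vertex: each subset of columns pinned to one
    of its bounds, remaining columns solved from the equality system (only
    accepted when that system has a unique exact solution).  Exponential —
    use on tiny models only.
    """
    S = fm.S.toarray()
    n = fm.n_cols
    j_obj = fm.col_index(objective_column)
    best = None
    cols = list(range(n))
    for k in range(n + 1):
        for nonbasic in itertools.combinations(cols, k):
            basic = [c for c in cols if c not in nonbasic]
            for bound_choice in itertools.product((0, 1), repeat=k):
                v = np.zeros(n)
                for c, b in zip(nonbasic, bound_choice):
                    v[c] = fm.lower[c] if b == 0 else fm.upper[c]
                if basic:
                    A = S[:, basic]
                    rhs = -S[:, nonbasic] @ v[list(nonbasic)] if k else np.zeros(S.shape[0])
                    if np.linalg.matrix_rank(A) < len(basic):
                        continue
                    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                    v[basic] = sol
                if np.max(np.abs(S @ v)) > 1e-8:
                    continue
                if np.any(v < fm.lower - 1e-9) or np.any(v > fm.upper + 1e-9):
                    continue
                val = v[j_obj]
                if best is None or val > best:
                    best = val
    return best


def chi2_statistic_oracle(table: np.ndarray) -> float:
    """Pearson chi-square by the direct sum over cells: sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    return float(((table - expected) ** 2 / expected).sum())


def signature_oracle(reaction) -> str:
    """Canonical form by brute force: the lexicographically smaller of the
    two orientations' sorted (compound, coefficient) side multisets, after
    cancelling compounds common to both sides."""
    def accumulate(terms):
        acc = {}
        for cid, coeff in terms:
            acc[cid] = acc.get(cid, 0.0) + coeff
        return acc

    left = accumulate(reaction.substrates)
    right = accumulate(reaction.products)
    for cid in sorted(set(left) & set(right)):
        m = min(left[cid], right[cid])
        left[cid] -= m
        right[cid] -= m
        if left[cid] == 0:
            del left[cid]
        if right[cid] == 0:
            del right[cid]
    a = sorted((c, round(k, 9)) for c, k in left.items())
    b = sorted((c, round(k, 9)) for c, k in right.items())
    return repr(min((a, b), (b, a)))
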