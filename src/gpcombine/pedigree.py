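"""Sire-only pedigree relationships for the polygenic model term.

Dams are unobserved in this pipeline, so the numerator relationship
matrix is built from sire links alone with unknown dams treated as
unrelated, non-inbred founders. Under that convention no animal is
inbred (F = 0 requires a known sire–dam pair), and the Mendelian
sampling variance of a sire-known animal is 1 − 0.25(1 + F_sire).
"""

from __future__ import annotations

import numpy as np

__all__ = ["sire_relationship", "sire_relationship_inverse", "topo_order"]


def topo_order(bull_ids, sire_ids) -> np.ndarray:
    """Permutation placing every sire before his sons."""
    ids = list(bull_ids)
    index = {b: i for i, b in enumerate(ids)}
    visited = np.zeros(len(ids), dtype=np.int8)  # 0 new, 1 active, 2 done
    order: list[int] = []

    def visit(i: int) -> None:
        stack = [i]
        while stack:
            j = stack[-1]
            if visited[j] == 2:
                stack.pop()
                continue
            s = sire_ids[j]
            si = index.get(s) if s is not None else None
            if si is not None and visited[si] == 0:
                if visited[j] == 1 and si in stack:
                    raise ValueError("pedigree contains a cycle")
                visited[j] = 1
                stack.append(si)
            else:
                visited[j] = 2
                order.append(j)
                stack.pop()

    sire_ids = list(sire_ids)
    for i in range(len(ids)):
        if visited[i] == 0:
            visit(i)
    return np.asarray(order, dtype=int)


def sire_relationship(bull_ids, sire_ids) -> np.ndarray:
    """Numerator relationship matrix A from sire links (dams unknown)."""
    ids = list(bull_ids)
    index = {b: i for i, b in enumerate(ids)}
    sires = list(sire_ids)
    n = len(ids)
    A = np.zeros((n, n))
    for i in topo_order(ids, sires):
        s = index.get(sires[i]) if sires[i] is not None else None
        if s is None:
            A[i, i] = 1.0
        else:
            A[i, :] = 0.5 * A[s, :]
            A[:, i] = A[i, :]
            A[i, i] = 1.0  # F_i = 0: dam unknown and unrelated
    return A


def sire_relationship_inverse(bull_ids, sire_ids) -> np.ndarray:
    """A⁻¹ via Henderson's rules specialised to sire-only pedigrees.

    For an animal with a known (non-inbred) sire the Mendelian sampling
    variance is 0.75, contributing α = 4/3 on the diagonal, −α/2 to the
    sire cross terms and α/4 to the sire diagonal; founders contribute 1.
    """
    ids = list(bull_ids)
    index = {b: i for i, b in enumerate(ids)}
    sires = list(sire_ids)
    n = len(ids)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s = index.get(sires[i]) if sires[i] is not None else None
        if s is None:
            Ainv[i, i] += 1.0
        else:
            alpha = 1.0 / 0.75
            Ainv[i, i] += alpha
            Ainv[i, s] -= 0.5 * alpha
            Ainv[s, i] -= 0.5 * alpha
            Ainv[s, s] += 0.25 * alpha
    return Ainv
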