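"""Independent brute-force oracles for the test suite.

Everything here is deliberately written as plain-Python double loops over
the defining formulas, with no reuse of the package's vectorized code, so
that agreement between the two routes is evidence of correctness.

Scale dictionaries map residue -> (h1, h2, h3) standardized values and are
built in conftest.py directly from the packaged CSV with the csv module.
"""

from __future__ import annotations

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# --- PseAAC -----------------------------------------------------------------

def naive_phi(a: str, b: str, sc: dict) -> float:
    return sum((sc[b][k] - sc[a][k]) ** 2 for k in range(3)) / 3.0


def naive_theta(seq: str, lag: int, sc: dict) -> float:
    terms = [naive_phi(seq[i], seq[i + lag], sc) for i in range(len(seq) - lag)]
    return sum(terms) / len(terms)


def naive_type1(seq: str, lam: int, w: float, sc: dict) -> list[float]:
    f = [seq.count(aa) / len(seq) for aa in ALPHABET]
    thetas = [naive_theta(seq, j, sc) for j in range(1, lam + 1)]
    den = sum(f) + w * sum(thetas)
    return [x / den for x in f] + [w * t / den for t in thetas]


def naive_tau(seq: str, r: int, sc: dict, as_printed: bool = False) -> list[float]:
    out = []
    for k in range(1, r + 1):
        pairs = [(seq[i], seq[i + k]) for i in range(len(seq) - k)]
        if as_printed:
            hydro = [sc[a][0] * sc[b][1] for a, b in pairs]
        else:
            hydro = [sc[a][0] * sc[b][0] for a, b in pairs]
        phil = [sc[a][1] * sc[b][1] for a, b in pairs]
        out.append(sum(hydro) / len(hydro))
        out.append(sum(phil) / len(phil))
    return out


def naive_type2(seq: str, r: int, w: float, sc: dict,
                as_printed: bool = False) -> list[float]:
    f = [seq.count(aa) / len(seq) for aa in ALPHABET]
    taus = naive_tau(seq, r, sc, as_printed)
    den = sum(f) + w * sum(taus)
    return [x / den for x in f] + [w * t / den for t in taus]


# --- Haar transform ---------------------------------------------------------

def haar2d_level1(a) -> tuple[list, list, list, list]:
    """Level-1 orthonormal 2-D Haar on an even-shaped nested list:
    per 2×2 block [[w, x], [y, z]] ->
    A=(w+x+y+z)/2, H=(w+x-y-z)/2, V=(w-x+y-z)/2, D=(w-x-y+z)/2."""
    rows, cols = len(a), len(a[0])
    assert rows % 2 == 0 and cols % 2 == 0
    A = [[0.0] * (cols // 2) for _ in range(rows // 2)]
    H = [[0.0] * (cols // 2) for _ in range(rows // 2)]
    V = [[0.0] * (cols // 2) for _ in range(rows // 2)]
    D = [[0.0] * (cols // 2) for _ in range(rows // 2)]
    for i in range(0, rows, 2):
        for j in range(0, cols, 2):
            w, x = a[i][j], a[i][j + 1]
            y, z = a[i + 1][j], a[i + 1][j + 1]
            A[i // 2][j // 2] = (w + x + y + z) / 2.0
            H[i // 2][j // 2] = (w + x - y - z) / 2.0
            V[i // 2][j // 2] = (w - x + y - z) / 2.0
            D[i // 2][j // 2] = (w - x - y + z) / 2.0
    return A, H, V, D


def haar2d_level1_inverse(A, H, V, D) -> list:
    rows, cols = 2 * len(A), 2 * len(A[0])
    a = [[0.0] * cols for _ in range(rows)]
    for i in range(len(A)):
        for j in range(len(A[0])):
            s, h, v, d = A[i][j], H[i][j], V[i][j], D[i][j]
            a[2 * i][2 * j] = (s + h + v + d) / 2.0
            a[2 * i][2 * j + 1] = (s + h - v - d) / 2.0
            a[2 * i + 1][2 * j] = (s - h + v - d) / 2.0
            a[2 * i + 1][2 * j + 1] = (s - h - v + d) / 2.0
    return a


def haar1d_level1(v) -> tuple[list, list]:
    """(a, b) pairs -> ((a+b)/√2, (a-b)/√2)."""
    s2 = math.sqrt(2.0)
    approx = [(v[i] + v[i + 1]) / s2 for i in range(0, len(v), 2)]
    detail = [(v[i] - v[i + 1]) / s2 for i in range(0, len(v), 2)]
    return approx, detail


def haar1d_level1_inverse(approx, detail) -> list:
    s2 = math.sqrt(2.0)
    out = []
    for a, d in zip(approx, detail):
        out.append((a + d) / s2)
        out.append((a - d) / s2)
    return out


def soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


# --- KNN / leave-one-out ----------------------------------------------------

def brute_knn(train_rows, train_labels, query, k):
    """Sorted explicit distance list; majority vote; vote tie -> label of the
    nearest neighbor with a tied label; equal distance -> lower index."""
    scored = []
    for idx, row in enumerate(train_rows):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query)))
        scored.append((d, idx))
    scored.sort()
    top = scored[:k]
    votes: dict = {}
    for _, idx in top:
        votes[train_labels[idx]] = votes.get(train_labels[idx], 0) + 1
    best = max(votes.values())
    tied = {lab for lab, c in votes.items() if c == best}
    if len(tied) == 1:
        return tied.pop()
    for _, idx in top:
        if train_labels[idx] in tied:
            return train_labels[idx]
    raise AssertionError


def brute_leave_one_out(rows, labels, k):
    preds = []
    for i in range(len(rows)):
        train = [r for j, r in enumerate(rows) if j != i]
        tl = [l for j, l in enumerate(labels) if j != i]
        preds.append(brute_knn(train, tl, rows[i], k))
    return preds
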