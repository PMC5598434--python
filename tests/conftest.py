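"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (dense grids, exhaustive
enumeration, string walks) and share no code with the implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from srscout.motifs import BLOSUM62, default_motif_panel
from srscout.physchem import DEFAULT_PK_TABLE

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def panel():
    return default_motif_panel()


# ---------------------------------------------------------------- pI oracle


def grid_pi(seq: str, pk=DEFAULT_PK_TABLE, step: float = 1e-4) -> float:
    """Dense-grid sign-change root of the net-charge curve."""
    ph = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pk.n_term_pk(seq[0])))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pk.c_term_pk(seq[-1]) - ph))
    for res in "HKR":
        n = seq.count(res)
        if n:
            charge = charge + n / (1.0 + 10.0 ** (ph - pk.side_chain[res]))
    for res in "DECY":
        n = seq.count(res)
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pk.side_chain[res] - ph))
    idx = np.where(np.diff(np.sign(charge)) != 0)[0]
    assert len(idx) == 1, "charge curve must cross zero exactly once"
    i = idx[0]
    return float(0.5 * (ph[i] + ph[i + 1]))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


# ------------------------------------------------- global-alignment oracle


def enumerate_global_score(
    a: str, b: str, matrix=None, gap_open: float = -2.0, gap_extend: float = -2.0
) -> float:
    """Max score over *all* global alignments by plain recursion.

    Affine convention: a gap of length L costs gap_open +
    (L - 1) * gap_extend.  No memoization — this is enumeration, kept
    independent of any DP implementation.
    """

    def sub(x: str, y: str) -> float:
        if matrix is None:
            return float(BLOSUM62[x, y])
        match, mismatch = matrix
        return match if x == y else mismatch

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if prev == "a" else gap_open
            best = max(best, cost + rec(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if prev == "b" else gap_open
            best = max(best, cost + rec(i, j + 1, "b"))
        return best

    return rec(0, 0, "m")


# --------------------------------------------------------------- ORF oracle


_STOPS = {"TAA", "TAG", "TGA"}


def walk_orfs(seq: str, min_nt: int, max_nt: int) -> set[tuple[int, int]]:
    """Every ATG walked codon-by-codon to its next in-frame stop."""
    found = set()
    n_runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "N":
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            if j - i >= 10:
                n_runs.append((i, j))
            i = j
        else:
            i += 1
    for p in range(len(seq) - 2):
        if seq[p : p + 3] != "ATG":
            continue
        q = p + 3
        while q + 3 <= len(seq):
            if seq[q : q + 3] in _STOPS:
                length = q + 3 - p
                if min_nt <= length <= max_nt and not any(
                    s < q + 3 and p < e for s, e in n_runs
                ):
                    found.add((p, q + 3))
                break
            q += 3
    return found


# --------------------------------------------------- clustering oracle


def transitive_closure_clusters(columns: list[int], window: int = 7) -> list[set[int]]:
    """Connected components of the pairwise |delta| <= window-1 graph."""
    parent = list(range(len(columns)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            if abs(columns[i] - columns[j]) <= window - 1:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(columns)):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
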