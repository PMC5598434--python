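"""Net charge and isoelectric point of protein sequences.

The isoelectric point (pI) is the pH at which a protein, on average,
carries no net electric charge.  Net charge is modelled as a sum of
independent Henderson–Hasselbalch terms, one per ionizable group:

    Q(pH) = sum_pos m_i / (1 + 10^(pH - pK_i))
          - sum_neg m_j / (1 + 10^(pK_j - pH))

with positive groups the N-terminal amine and H, K, R side chains, and
negative groups the C-terminal carboxyl and D, E, C, Y side chains.
Q is strictly decreasing in pH, so the root is unique; it is bracketed
by bisection on [0, 14].

The default dissociation constants are the Bjellqvist set used by the
ExPASy lineage of tools, including the residue-specific pK overrides for
the terminal groups.  Signal peptides are excluded from the calculation
when a cleavage boundary is supplied (mature-sequence convention used
for secreted RNases).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from srscout.seq_io import ProteinRecord

POSITIVE_RESIDUES = ("H", "K", "R")
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")

# Bjellqvist side-chain and terminal pK values (ExPASy dialect).
_SIDE_CHAIN_PK = {
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.00,
    "Y": 10.00,
    "K": 10.00,
    "R": 12.00,
}
_N_TERM_DEFAULT = 7.50
_N_TERM_OVERRIDES = {
    "A": 7.59,
    "M": 7.00,
    "S": 6.93,
    "P": 8.36,
    "T": 6.82,
    "V": 7.44,
    "E": 7.70,
}
_C_TERM_DEFAULT = 3.55
_C_TERM_OVERRIDES = {"D": 4.55, "E": 4.75}


@dataclass
class PkTable:
    """Dissociation constants for ionizable groups.

    ``side_chain`` must cover D, E, H, C, Y, K, R.  Terminal groups use
    the default pK unless the terminal residue has an override.  All pK
    values must lie in (0, 14).
    """

    side_chain: dict[str, float] = field(default_factory=lambda: dict(_SIDE_CHAIN_PK))
    n_term_default: float = _N_TERM_DEFAULT
    n_term_overrides: dict[str, float] = field(
        default_factory=lambda: dict(_N_TERM_OVERRIDES)
    )
    c_term_default: float = _C_TERM_DEFAULT
    c_term_overrides: dict[str, float] = field(
        default_factory=lambda: dict(_C_TERM_OVERRIDES)
    )

    def __post_init__(self) -> None:
        missing = set("DEHCYKR") - set(self.side_chain)
        if missing:
            raise ValueError(f"PkTable missing side-chain pKs for {sorted(missing)}")
        for value in (
            *self.side_chain.values(),
            self.n_term_default,
            self.c_term_default,
            *self.n_term_overrides.values(),
            *self.c_term_overrides.values(),
        ):
            if not (0.0 < value < 14.0):
                raise ValueError(f"pK value {value} outside (0, 14)")

    def n_term_pk(self, residue: str) -> float:
        return self.n_term_overrides.get(residue, self.n_term_default)

    def c_term_pk(self, residue: str) -> float:
        return self.c_term_overrides.get(residue, self.c_term_default)


DEFAULT_PK_TABLE = PkTable()


def mature_sequence(rec: ProteinRecord) -> str:
    """Strip the signal peptide when a cleavage boundary is present."""
    if rec.signal_peptide_end is None:
        return rec.seq
    mature = rec.seq[rec.signal_peptide_end :]
    if not mature:
        raise ValueError(f"{rec.id}: signal-peptide boundary leaves no mature chain")
    return mature


def net_charge(seq: str, pH: float, pk: PkTable = DEFAULT_PK_TABLE) -> float:
    """Average net charge of ``seq`` at ``pH``.

    X residues carry no charge.  Both termini always contribute.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq)
    charge = 1.0 / (1.0 + 10.0 ** (pH - pk.n_term_pk(seq[0])))
    for res in POSITIVE_RESIDUES:
        if counts[res]:
            charge += counts[res] / (1.0 + 10.0 ** (pH - pk.side_chain[res]))
    charge -= 1.0 / (1.0 + 10.0 ** (pk.c_term_pk(seq[-1]) - pH))
    for res in NEGATIVE_RESIDUES:
        if counts[res]:
            charge -= counts[res] / (1.0 + 10.0 ** (pk.side_chain[res] - pH))
    return charge


def isoelectric_point(
    seq: str, pk: PkTable = DEFAULT_PK_TABLE, tol: float = 0.01
) -> float:
    """pH at which ``net_charge`` crosses zero, by bisection on [0, 14].

    The bracket is narrowed until its width falls below ``tol`` (default
    0.01 pH); report to two decimals for tabulation.
    """
    lo, hi = 0.0, 14.0
    q_lo = net_charge(seq, lo, pk)
    q_hi = net_charge(seq, hi, pk)
    if q_lo < 0.0 or q_hi > 0.0:
        raise ValueError("net charge does not change sign on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def record_pi(
    rec: ProteinRecord, pk: PkTable = DEFAULT_PK_TABLE, tol: float = 0.01
) -> float:
    """pI of the mature chain of a protein record."""
    return isoelectric_point(mature_sequence(rec), pk, tol)


def read_pk_table(path) -> PkTable:
    """Load a pK override table from two-column TSV (group, pK).

    Group names: single residues for side chains, ``Nterm``/``Cterm``
    for the terminal defaults, ``Nterm_X``/``Cterm_X`` for
    terminal-residue overrides.
    """
    table = PkTable()
    with open(path) if not hasattr(path, "read") else path as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            group, value = line.split("\t")
            value = float(value)
            if group == "Nterm":
                table.n_term_default = value
            elif group == "Cterm":
                table.c_term_default = value
            elif group.startswith("Nterm_"):
                table.n_term_overrides[group[6:]] = value
            elif group.startswith("Cterm_"):
                table.c_term_overrides[group[6:]] = value
            else:
                table.side_chain[group] = value
    return PkTable(
        side_chain=table.side_chain,
        n_term_default=table.n_term_default,
        n_term_overrides=table.n_term_overrides,
        c_term_default=table.c_term_default,
        c_term_overrides=table.c_term_overrides,
    )
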