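"""Per-protein descriptors: length, molecular weight, isoelectric point.

Molecular weight uses average residue masses plus one water; pI uses the
Bjellqvist pKa set by default (N-/C-termini and the D, E, C, Y, H, K, R side
chains) with bisection on the monotone net-charge curve.  Both tables ship
as TSV data files and are swappable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class PhysChem:
    length: int
    mw: float     # kDa
    pi: float


@dataclass(frozen=True)
class PkaTable:
    n_term: float
    c_term: float
    side_chains: dict   # residue -> (pka, +1 or -1 sign)


def _data(name: str):
    return (importlib.resources.files("ltpscan.data") / name).open()


def load_mass_table(path: str | Path | None = None) -> tuple[dict, float]:
    df = pd.read_csv(_data("aa_masses.tsv") if path is None else path, sep="\t")
    masses = dict(zip(df["residue"], df["average_mass"]))
    water = masses.pop("water")
    return masses, water


def load_pka_table(path: str | Path | None = None) -> PkaTable:
    df = pd.read_csv(_data("pka_bjellqvist.tsv") if path is None else path, sep="\t")
    rows = {r["group"]: (float(r["pka"]), 1 if r["charge"] == "positive" else -1)
            for _, r in df.iterrows()}
    n_term = rows.pop("n_term")[0]
    c_term = rows.pop("c_term")[0]
    return PkaTable(n_term=n_term, c_term=c_term, side_chains=rows)


_MASSES, _WATER = load_mass_table()
_PKA = load_pka_table()


def molecular_weight(seq: str, mass_table: dict | None = None,
                     water: float | None = None) -> float:
    """Average molecular weight in kDa: sum of residue masses + one water.

    ``X`` and other non-standard residues are rejected (mass undefined).
    """
    masses = _MASSES if mass_table is None else mass_table
    w = _WATER if water is None else water
    total = w
    for i, aa in enumerate(seq):
        if aa not in masses:
            raise ValueError(f"residue {aa!r} at position {i} has no defined mass")
        total += masses[aa]
    return total / 1000.0


def net_charge(seq: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge at ``ph``: sum of positive-group fractions minus
    negative-group fractions (Henderson–Hasselbalch)."""
    table = _PKA if pka is None else pka
    z = 1.0 / (1.0 + 10.0 ** (ph - table.n_term))
    z -= 1.0 / (1.0 + 10.0 ** (table.c_term - ph))
    for aa in seq:
        if aa in table.side_chains:
            pk, sign = table.side_chains[aa]
            if sign > 0:
                z += 1.0 / (1.0 + 10.0 ** (ph - pk))
            else:
                z -= 1.0 / (1.0 + 10.0 ** (pk - ph))
    return z


def isoelectric_point(seq: str, pka: PkaTable | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Z(pH) is monotone non-increasing, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    z_lo = net_charge(seq, lo, pka)
    if z_lo <= 0:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        z = net_charge(seq, mid, pka)
        if abs(z) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def characterize(seq: str) -> PhysChem:
    return PhysChem(length=len(seq), mw=molecular_weight(seq),
                    pi=isoelectric_point(seq))
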