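"""Net charge versus pH, theoretical isoelectric points and acidity percentiles.

The charge model is the per-group Henderson-Hasselbalch treatment: each chain
carries exactly one free N-terminal amino group and one free C-terminal
carboxyl group, plus one ionizable group per K, R, H (basic) and per D, E, C,
Y (acidic) residue.  At a given pH the fractional charge of a basic group with
constant pK is ``1 / (1 + 10**(pH - pK))`` and that of an acidic group is
``-1 / (1 + 10**(pK - pH))``; the protein net charge is the sum over groups,
in elementary-charge units.  Because every term is strictly decreasing in pH,
the net charge has a unique root in (0, 14) — the theoretical isoelectric
point — which is located by bisection.

The default ionization constants are the EMBOSS pK set::

    Amino 8.6   Carboxyl 3.6   C 8.5   D 3.9   E 4.1
    H 6.5       K 10.8         R 12.5  Y 10.1

No post-translational modifications are modelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import json

import numpy as np

from .seqio import PROTEIN_ALPHABET, AlphabetError, ProteinRecord

_BASIC_RESIDUES = "KRH"
_ACIDIC_RESIDUES = "DECY"
_GROUP_NAMES = ("Amino", "Carboxyl", "C", "D", "E", "H", "K", "R", "Y")


@dataclass(frozen=True)
class PKSet:
    """Ionization constants (pH units) for termini and ionizable side chains."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(_GROUP_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"pK set missing groups: {sorted(missing)}")
        for name in _GROUP_NAMES:
            pk = float(self.values[name])
            if not np.isfinite(pk) or not 0.0 < pk < 14.0:
                raise ValueError(f"pK for {name} out of range (0, 14): {pk}")

    def __getitem__(self, group: str) -> float:
        return float(self.values[group])

    @classmethod
    def from_json(cls, path: str | Path) -> "PKSet":
        with open(path) as fh:
            return cls(json.load(fh))


#: EMBOSS ionization constants (the default pK model).
EMBOSS_PKS = PKSet({
    "Amino": 8.6, "Carboxyl": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
})


@dataclass
class ChargeProfile:
    """Net charge evaluated on a pH grid for one protein."""

    protein_id: str
    ph: np.ndarray
    charge: np.ndarray


def _group_counts(protein: ProteinRecord) -> tuple[Counter, int]:
    illegal = set(protein.sequence) - PROTEIN_ALPHABET
    # X (masked ambiguity) carries no ionizable group and is skipped
    illegal -= {"X"}
    if illegal:
        raise AlphabetError(
            f"record {protein.id!r}: non-standard residues {sorted(illegal)}"
        )
    counts = Counter(protein.sequence)
    n_masked = counts.pop("X", 0)
    return counts, n_masked


def net_charge(protein: ProteinRecord, ph: float | np.ndarray,
               pks: PKSet = EMBOSS_PKS) -> float | np.ndarray:
    """Net charge of ``protein`` at ``ph``, in elementary-charge units.

    ``ph`` may be a scalar or an array (vectorized evaluation on a grid).
    """
    counts, _ = _group_counts(protein)
    ph = np.asarray(ph, dtype=float)
    basic = np.zeros_like(ph)
    for group, n in [("Amino", 1)] + [(r, counts[r]) for r in _BASIC_RESIDUES]:
        if n:
            basic += n / (1.0 + 10.0 ** (ph - pks[group]))
    acidic = np.zeros_like(ph)
    for group, n in [("Carboxyl", 1)] + [(r, counts[r]) for r in _ACIDIC_RESIDUES]:
        if n:
            acidic += n / (1.0 + 10.0 ** (pks[group] - ph))
    result = basic - acidic
    return float(result) if result.ndim == 0 else result


def charge_profile(protein: ProteinRecord, pks: PKSet = EMBOSS_PKS,
                   ph_min: float = 0.1, ph_max: float = 13.9,
                   n: int = 139) -> ChargeProfile:
    """Evaluate the net charge on an evenly spaced pH grid."""
    grid = np.linspace(ph_min, ph_max, n)
    return ChargeProfile(protein.id, grid, net_charge(protein, grid, pks))


def isoelectric_point(protein: ProteinRecord, pks: PKSet = EMBOSS_PKS,
                      tol: float = 1e-4) -> float:
    """The pH at which the net charge is zero, found by bisection on (0, 14).

    The charge is strictly decreasing in pH for any chain (the termini alone
    guarantee at least one basic and one acidic group), so the root is unique.
    The returned value is within ``tol`` of the true root.
    """
    lo, hi = 0.0, 14.0
    # charge(lo) > 0 > charge(hi) always holds with both termini present
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pks) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def acidity_percentile(query_pi: float, proteome_pis: Iterable[float]) -> float:
    """Percentage of proteome pI values strictly greater than ``query_pi``.

    "More acidic than P% of the proteome": ties count as not-more-acidic.
    """
    values = np.asarray(list(proteome_pis), dtype=float)
    if values.size == 0:
        raise ValueError("proteome pI collection is empty")
    return 100.0 * float(np.count_nonzero(values > query_pi)) / values.size
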