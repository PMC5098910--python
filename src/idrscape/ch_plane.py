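"""Charge-hydropathy classification of intrinsically disordered regions.

A protein (or an IDR cut from one) is summarized by two numbers: its mean
scaled Kyte-Doolittle hydropathy <H> (window-averaged, affinely rescaled to
[0, 1]) and its absolute mean net charge <R> (Henderson-Hasselbalch net charge
at pH 7.0 divided by chain length).  In the (<H>, <R>) plane natively unfolded
proteins fall on the low-hydropathy / high-charge side of the empirical
boundary line

    <H>_b = (<R> + 1.151) / 2.785

and natively folded proteins on the other; a chain is called disordered iff
<H> < <H>_b (points exactly on the boundary are called folded).

The caller supplies the sequences to classify; this module does not delimit
IDRs within longer chains and does not predict per-residue disorder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .physchem import EMBOSS_PKS, PKSet, net_charge
from .seqio import ProteinRecord

#: Kyte-Doolittle hydropathy scale (raw, spanning [-4.5, +4.5]).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Boundary line coefficients: <H>_b = (<R> + _B_INTERCEPT) / _B_SLOPE.
_B_INTERCEPT = 1.151
_B_SLOPE = 2.785


@dataclass
class HydropathyProfile:
    """Per-residue scaled hydropathy values for one protein."""

    protein_id: str
    values: np.ndarray
    window: int


@dataclass(frozen=True)
class CHPoint:
    """A protein's position in the charge-hydropathy plane and its call."""

    protein_id: str
    H: float
    R: float
    call: Literal["folded", "disordered"]


def scaled_kd(residue: str) -> float:
    """Kyte-Doolittle value rescaled affinely from [-4.5, 4.5] to [0, 1]."""
    return (KYTE_DOOLITTLE[residue] + 4.5) / 9.0


def kd_profile(protein: ProteinRecord, window: int = 5) -> HydropathyProfile:
    """Windowed mean of scaled Kyte-Doolittle values, one per residue.

    The window is centered; at the termini it shrinks (is truncated) so the
    profile has exactly one value per residue.  ``window`` must be odd.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= len(protein):
        raise ValueError(f"window {window} outside [1, {len(protein)}]")
    raw = np.array([scaled_kd(c) for c in protein.sequence if c != "X"])
    if raw.size == 0:
        raise ValueError(f"record {protein.id!r}: no scorable residues")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(raw.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, raw.size)
    values = (csum[hi] - csum[lo]) / (hi - lo)
    return HydropathyProfile(protein.id, values, window)


def mean_scaled_hydropathy(profile: HydropathyProfile) -> float:
    """Mean of the windowed scaled hydropathy over all residues."""
    if profile.values.size == 0:
        raise ValueError("empty hydropathy profile")
    return float(np.mean(profile.values))


def mean_net_charge(protein: ProteinRecord, pks: PKSet = EMBOSS_PKS, *,
                    approximate: bool = False) -> float:
    """Absolute mean net charge: |net charge at pH 7.0| / chain length.

    By default the full Henderson-Hasselbalch charge is used.  With
    ``approximate=True`` the common integer-count shortcut
    |#K + #R - #D - #E| / length is used instead.
    """
    n = len(protein)
    if approximate:
        s = protein.sequence
        q = s.count("K") + s.count("R") - s.count("D") - s.count("E")
        return abs(q) / n
    return abs(net_charge(protein, 7.0, pks)) / n


def boundary_hydropathy(R: float) -> float:
    """The boundary <H>_b separating folded from disordered at charge R."""
    return (R + _B_INTERCEPT) / _B_SLOPE


def classify(H: float, R: float) -> Literal["folded", "disordered"]:
    """Disordered iff H < (R + 1.151)/2.785; the boundary itself is folded."""
    if not 0.0 <= H <= 1.0:
        raise ValueError(f"H must lie in [0, 1], got {H}")
    if R < 0.0:
        raise ValueError(f"R must be non-negative, got {R}")
    return "disordered" if H < boundary_hydropathy(R) else "folded"


def ch_point(protein: ProteinRecord, pks: PKSet = EMBOSS_PKS,
             window: int = 5) -> CHPoint:
    """Compute (<H>, <R>) for a protein and classify it."""
    H = mean_scaled_hydropathy(kd_profile(protein, window))
    R = mean_net_charge(protein, pks)
    return CHPoint(protein.id, H, R, classify(H, R))


def ch_points(proteins: Iterable[ProteinRecord], pks: PKSet = EMBOSS_PKS,
              window: int = 5) -> list[CHPoint]:
    return [ch_point(p, pks, window) for p in proteins]


def plot_ch_plane(points: Iterable[CHPoint], ax=None):
    """Scatter CH points with the empirical folded/disordered boundary line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pts = list(points)
    for call, marker, color in [("disordered", "o", "tab:orange"),
                                ("folded", "^", "tab:blue")]:
        sel = [p for p in pts if p.call == call]
        if sel:
            ax.scatter([p.H for p in sel], [p.R for p in sel],
                       marker=marker, s=18, color=color, label=call)
    h = np.linspace(0, 1, 50)
    ax.plot(h, _B_SLOPE * h - _B_INTERCEPT, "k--", lw=1, label="boundary")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, max(0.6, max((p.R for p in pts), default=0.6) * 1.1))
    ax.set_xlabel("mean scaled hydropathy $\\langle H\\rangle$")
    ax.set_ylabel("absolute mean net charge $\\langle R\\rangle$")
    ax.legend(frameon=False, fontsize=8)
    return ax
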