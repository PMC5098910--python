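"""Amino-acid composition enrichment with bootstrap error bars.

For a query dataset (e.g. the pooled IDRs of a protein family) and a reference
dataset of ordered proteins, the enrichment of residue x is

    (C_x - C_order) / C_order

where C_x is the residue's relative frequency in the query and C_order its
frequency in the reference: the normalized excess of that residue.  Values
above zero are enrichments, below zero depletions, and -1 is total absence.
Error bars are the standard deviations of the enrichment over bootstrap
resamples of both datasets (residues resampled with replacement,
independently, at the original dataset sizes).

Reference compositions may come from any FASTA dataset or from a bundled
frequency table; residues with zero reference frequency have undefined
enrichment and are reported as NaN, never as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import ProteinRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class CompositionVector:
    """Relative residue frequencies plus the residue count they summarize."""

    frequencies: Mapping[str, float]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("composition requires at least one residue")
        freqs = np.array([self.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS])
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS])


@dataclass
class EnrichmentResult:
    """Per-residue enrichment and bootstrap SD for a query/reference pair."""

    enrichment: "pd.Series"
    bootstrap_sd: "pd.Series | None"
    query_tag: str
    reference_tag: str
    n_boot: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"enrichment": self.enrichment})
        if self.bootstrap_sd is not None:
            df["bootstrap_sd"] = self.bootstrap_sd
        return df


def composition(records: Iterable[ProteinRecord]) -> CompositionVector:
    """Pooled residue frequencies over a dataset of sequences.

    X residues (masked ambiguities) are excluded from the counts.
    """
    counts = np.zeros(20, dtype=np.int64)
    for rec in records:
        for c in rec.sequence:
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no standard residues in input dataset")
    return CompositionVector(dict(zip(AMINO_ACIDS, counts / total)), total)


def enrichment(query: CompositionVector,
               reference: CompositionVector) -> pd.Series:
    """Elementwise (C_x - C_order)/C_order; NaN where the reference is zero."""
    cx = query.as_array()
    cref = reference.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(cref > 0, (cx - cref) / np.where(cref > 0, cref, 1.0), np.nan)
    return pd.Series(e, index=list(AMINO_ACIDS), name="enrichment")


def _resample_freqs(freqs: np.ndarray, size: int, n_boot: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Bootstrap frequencies: multinomial residue resampling at original size."""
    return rng.multinomial(size, freqs, size=n_boot) / size


def bootstrap_sd(query_records: Iterable[ProteinRecord],
                 reference_records: Iterable[ProteinRecord],
                 n_boot: int = 10000, seed: int = 0, *,
                 unit: str = "residue") -> pd.Series:
    """Bootstrap standard deviation of the per-residue enrichment.

    Residues (default) or whole sequences (``unit="sequence"``) are resampled
    with replacement, independently for query and reference, each at its
    original dataset size; the enrichment is recomputed per replicate and the
    per-residue SD over replicates returned.  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    query_records = list(query_records)
    reference_records = list(reference_records)
    rng = np.random.default_rng(seed)
    if unit == "residue":
        q = composition(query_records)
        r = composition(reference_records)
        qf = _resample_freqs(q.as_array(), q.count, n_boot, rng)
        rf = _resample_freqs(r.as_array(), r.count, n_boot, rng)
    elif unit == "sequence":
        qf = _sequence_bootstrap(query_records, n_boot, rng)
        rf = _sequence_bootstrap(reference_records, n_boot, rng)
    else:
        raise ValueError(f"unknown bootstrap unit {unit!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(rf > 0, (qf - rf) / np.where(rf > 0, rf, 1.0), np.nan)
    sd = np.full(20, np.nan)
    defined = ~np.isnan(e).all(axis=0)
    sd[defined] = np.nanstd(e[:, defined], axis=0, ddof=1)
    return pd.Series(sd, index=list(AMINO_ACIDS), name="bootstrap_sd")


def _sequence_bootstrap(records: list[ProteinRecord], n_boot: int,
                        rng: np.random.Generator) -> np.ndarray:
    per_seq = np.stack([
        np.bincount([_AA_INDEX[c] for c in r.sequence if c in _AA_INDEX],
                    minlength=20)
        for r in records
    ])
    out = np.empty((n_boot, 20))
    n = len(records)
    for b in range(n_boot):
        counts = per_seq[rng.integers(0, n, size=n)].sum(axis=0)
        out[b] = counts / counts.sum()
    return out


def enrichment_analysis(query_records: Iterable[ProteinRecord],
                        reference: "CompositionVector | Iterable[ProteinRecord]",
                        n_boot: int | None = 10000, seed: int = 0,
                        query_tag: str = "query",
                        reference_tag: str = "reference") -> EnrichmentResult:
    """Full enrichment analysis: point estimates plus bootstrap error bars.

    Bootstrap SDs are computed only when the reference is given as records
    (a frequency-table reference has no resampling unit); pass ``n_boot=None``
    to skip the bootstrap entirely.
    """
    query_records = list(query_records)
    q = composition(query_records)
    if isinstance(reference, CompositionVector):
        ref_vec, ref_records = reference, None
    else:
        ref_records = list(reference)
        ref_vec = composition(ref_records)
    e = enrichment(q, ref_vec)
    sd = None
    if n_boot is not None and ref_records is not None:
        sd = bootstrap_sd(query_records, ref_records, n_boot, seed)
    return EnrichmentResult(e, sd, query_tag, reference_tag, n_boot, seed)


def load_reference(tag: str) -> CompositionVector:
    """Load a bundled reference composition table.

    Available tags: ``ordered_like`` and ``disordered_like`` — synthetic
    stand-in frequency vectors emulating an ordered (PDB-derived-style) and a
    disordered (DisProt-style) dataset respectively; they are package
    constants, not measurements of those databases.
    """
    fname = f"data/{tag}_composition.synthetic.tsv"
    ref = resources.files("idrscape").joinpath(fname)
    if not ref.is_file():
        raise ValueError(f"no bundled reference composition named {tag!r}")
    with resources.as_file(ref) as path:
        return read_frequency_table(path)


def read_frequency_table(path: str | Path) -> CompositionVector:
    """Read a two-column (residue, frequency) TSV; '#' lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["residue", "frequency"])
    freqs = dict(zip(df["residue"], df["frequency"].astype(float)))
    # a frequency table summarizes an external dataset of unknown size; use a
    # nominal count of 1 (the count only matters for residue-level bootstraps)
    return CompositionVector(freqs, max(1, int(df.attrs.get("count", 1))))


def plot_enrichment(result: EnrichmentResult, ax=None):
    """Bar plot of per-residue enrichment with bootstrap error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    e = result.enrichment
    err = result.bootstrap_sd if result.bootstrap_sd is not None else None
    colors = ["tab:red" if v > 0 else "tab:blue" for v in e]
    ax.bar(e.index, e.values, yerr=None if err is None else err.values,
           color=colors, capsize=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("$(C_x - C_{order})/C_{order}$")
    ax.set_title(f"{result.query_tag} vs {result.reference_tag}", fontsize=9)
    return ax
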