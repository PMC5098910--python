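"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of a :class:`GeneratorSpec` (seed
included): proteomes with controlled residue composition, sequences with
motifs or tandem repeats planted at recorded offsets, domain-hit tables with
known ground-truth architectures, block-structured HMM-match probability
matrices, and noisy step-function disorder tracks.  Ground-truth tables
accompany every output so downstream calls can be scored without re-deriving
the planted features.

The composition profiles are synthetic package constants that mirror the
qualitative character of ordered versus disordered datasets (disordered:
enriched in D/E/S/T/P/K/G/Q, depleted in W/C/F/I/Y/V/L/M); they are not
measurements of any external database.

One root seed drives everything; each generator derives its own child stream
from the root seed and a fixed component label, so adding a generator never
perturbs the outputs of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm_cluster import ProbabilityMatrix
from .motifs_tracks import ScoreTrack
from .ortholog_triage import DOMAIN_QUERIES, DomainHit
from .seqio import ProteinRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Synthetic disordered-like residue frequencies (charged/polar-rich).
DISORDERED_LIKE: dict[str, float] = {
    "A": 0.070, "C": 0.000, "D": 0.090, "E": 0.120, "F": 0.005,
    "G": 0.100, "H": 0.020, "I": 0.020, "K": 0.080, "L": 0.030,
    "M": 0.010, "N": 0.050, "P": 0.090, "Q": 0.060, "R": 0.040,
    "S": 0.110, "T": 0.070, "V": 0.030, "W": 0.000, "Y": 0.005,
}

#: Synthetic ordered-like residue frequencies (hydrophobe-rich, globular).
ORDERED_LIKE: dict[str, float] = {
    "A": 0.080, "C": 0.020, "D": 0.050, "E": 0.060, "F": 0.045,
    "G": 0.070, "H": 0.022, "I": 0.060, "K": 0.060, "L": 0.100,
    "M": 0.024, "N": 0.044, "P": 0.045, "Q": 0.037, "R": 0.050,
    "S": 0.060, "T": 0.055, "V": 0.070, "W": 0.014, "Y": 0.034,
}

_PROFILES: dict[str, dict[str, float]] = {
    "ordered_like": ORDERED_LIKE,
    "disordered_like": DISORDERED_LIKE,
    "uniform": {aa: 0.05 for aa in AMINO_ACIDS},
}


def child_rng(seed: int, label: str) -> np.random.Generator:
    """A child RNG stream derived from the root seed and a fixed label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class PlantedMotif:
    """A literal subsequence spliced into one generated sequence."""

    seq_index: int
    offset: int
    motif: str


@dataclass(frozen=True)
class PlantedRepeat:
    """``n_copies`` tandem copies of cycled repeat units at one offset."""

    seq_index: int
    offset: int
    units: tuple[str, ...]
    n_copies: int


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything a generator needs; equal specs give byte-identical output."""

    seed: int = 0
    # sequence generation
    n_sequences: int = 10
    length: int | tuple[int, int] = 300
    profile: str | Mapping[str, float] = "uniform"
    planted_motifs: tuple[PlantedMotif, ...] = ()
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    # hit-table generation
    n_proteins: int = 200
    architecture_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"full": 0.4, "partial": 0.3, "none": 0.3})
    # probability-matrix generation
    block_sizes: tuple[int, ...] = (5, 5)
    within_block_p: tuple[float, float] = (45.0, 5.0)   # Beta params, mean 0.9
    between_block_p: tuple[float, float] = (1.0, 99.0)  # Beta params, mean 0.01
    # score-track generation
    track_length: int = 300
    track_boundaries: tuple[int, ...] = (100, 200)
    track_levels: tuple[float, float] = (0.2, 0.8)
    track_sigma: float = 0.1


def _profile_vector(profile: str | Mapping[str, float]) -> np.ndarray:
    if isinstance(profile, str):
        try:
            profile = _PROFILES[profile]
        except KeyError:
            raise ValueError(f"unknown composition profile {profile!r}")
    v = np.array([profile.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("profile frequencies must be non-negative and sum to 1")
    return v


def gen_sequences(spec: GeneratorSpec
                  ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """i.i.d.-residue sequences with planted motifs/repeats at known offsets.

    Returns the records and a ground-truth table with one row per planted
    feature (columns: protein, kind, start, end, feature).
    """
    rng = child_rng(spec.seed, "sequences")
    probs = _profile_vector(spec.profile)
    aas = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    lengths = (
        np.full(spec.n_sequences, spec.length, dtype=int)
        if isinstance(spec.length, int)
        else rng.integers(spec.length[0], spec.length[1] + 1,
                          size=spec.n_sequences)
    )
    planted: dict[int, list[tuple[int, str, str]]] = {}
    for pm in spec.planted_motifs:
        planted.setdefault(pm.seq_index, []).append((pm.offset, pm.motif, "motif"))
    for pr in spec.planted_repeats:
        block = "".join(pr.units[i % len(pr.units)] for i in range(pr.n_copies))
        planted.setdefault(pr.seq_index, []).append((pr.offset, block, "repeat"))
    for i in range(spec.n_sequences):
        L = int(lengths[i])
        seq = list(aas[rng.choice(20, size=L, p=probs)])
        for offset, block, kind in planted.get(i, []):
            if offset < 0 or offset + len(block) > L:
                raise ValueError(
                    f"planted {kind} [{offset}, {offset + len(block)}) exceeds "
                    f"sequence {i} of length {L}"
                )
            seq[offset:offset + len(block)] = list(block)
            truth_rows.append({"protein": f"synth{i:04d}", "kind": kind,
                               "start": offset, "end": offset + len(block),
                               "feature": block})
        records.append(ProteinRecord(f"synth{i:04d}", "".join(seq),
                                     f"synthetic {spec.profile} profile"))
    truth = pd.DataFrame(truth_rows,
                         columns=["protein", "kind", "start", "end", "feature"])
    return records, truth


def _log_uniform(rng: np.random.Generator, lo: float, hi: float,
                 size: int | None = None) -> np.ndarray | float:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def gen_hit_table(spec: GeneratorSpec
                  ) -> tuple[list[DomainHit], pd.DataFrame]:
    """Domain-hit tables with known ground-truth architecture per protein.

    ``full`` proteins get significant hits (E log-uniform in [1e-12, 1e-6])
    to all three domains; ``partial`` to protease and zinc finger, plus an
    insignificant decoy HMG-box hit (E in [1e-4, 1]); ``none`` proteins get a
    significant HMG-box hit only, plus decoys — after strict filtering they
    carry neither protease nor zinc finger.  The truth table records the
    intended status of every protein.
    """
    freqs = dict(spec.architecture_freqs)
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("architecture frequencies must sum to 1")
    rng = child_rng(spec.seed, "hit_table")
    statuses = list(freqs)
    probs = np.array([freqs[s] for s in statuses])
    protease, zinc, hmg = DOMAIN_QUERIES
    hits: list[DomainHit] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_proteins):
        status = statuses[rng.choice(len(statuses), p=probs)]
        pid = f"prot{i:04d}"
        species = f"species_{i:04d}"
        length = int(rng.integers(300, 801))
        common = dict(species=species, strain=None, gene=f"gene_{i:04d}",
                      length=length)

        def hit(domain: str, lo: float, hi: float) -> DomainHit:
            return DomainHit(pid, domain, float(_log_uniform(rng, lo, hi)),
                             **common)

        if status == "full":
            hits += [hit(d, 1e-12, 1e-6) for d in (protease, zinc, hmg)]
        elif status == "partial":
            hits += [hit(protease, 1e-12, 1e-6), hit(zinc, 1e-12, 1e-6),
                     hit(hmg, 1e-4, 1.0)]
        elif status == "none":
            hits += [hit(hmg, 1e-12, 1e-6),
                     hit(protease, 1e-4, 1.0), hit(zinc, 1e-4, 1.0)]
        else:
            raise ValueError(f"unknown architecture {status!r}")
        truth_rows.append({"protein": pid, "species": species,
                           "status": status, "length": length})
    return hits, pd.DataFrame(truth_rows)


def gen_block_matrix(spec: GeneratorSpec
                     ) -> tuple[ProbabilityMatrix, list[int]]:
    """Block-structured symmetric probability matrix with planted clusters.

    Within-block and between-block probabilities are Beta-distributed with
    the spec's parameters (defaults: mean 0.9 within, mean 0.01 between);
    diagonal entries are 1.  Returns the matrix and per-item block labels.
    """
    if len(spec.block_sizes) < 1:
        raise ValueError("need at least one block")
    rng = child_rng(spec.seed, "block_matrix")
    n = int(sum(spec.block_sizes))
    blocks: list[int] = []
    for b, size in enumerate(spec.block_sizes):
        blocks += [b] * size
    blocks_arr = np.array(blocks)
    same = blocks_arr[:, None] == blocks_arr[None, :]
    aw, bw = spec.within_block_p
    ab, bb = spec.between_block_p
    within = rng.beta(aw, bw, size=(n, n))
    between = rng.beta(ab, bb, size=(n, n))
    P = np.where(same, within, between)
    P = np.triu(P, 1)
    P = P + P.T
    np.fill_diagonal(P, 1.0)
    labels = [f"fam{b}_{i:03d}" for i, b in enumerate(blocks)]
    return ProbabilityMatrix(labels, P), blocks


def gen_score_track(spec: GeneratorSpec) -> tuple[ScoreTrack, list[int]]:
    """Noisy step-function disorder track with recorded segment boundaries.

    Levels alternate between the two spec levels (default 0.2/0.8) at each
    boundary; Gaussian noise with the spec sigma (default 0.1) is added.
    """
    rng = child_rng(spec.seed, "score_track")
    lo, hi = spec.track_levels
    x = np.empty(spec.track_length)
    bounds = [0, *spec.track_boundaries, spec.track_length]
    for k in range(len(bounds) - 1):
        x[bounds[k]:bounds[k + 1]] = lo if k % 2 == 0 else hi
    x = x + rng.normal(0.0, spec.track_sigma, size=spec.track_length)
    track = ScoreTrack("synthetic_track", tuple(float(v) for v in x))
    return track, list(spec.track_boundaries)
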