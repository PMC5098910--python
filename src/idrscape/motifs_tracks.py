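"""Short-linear-motif scanning and per-residue score-track smoothing.

Two motifs of interest:

* the SUMO-interacting motif (SIM) — a hydrophobic core flanked by acidic or
  phosphorylatable residues, as the ELM-style pattern
  ``[DEST]{0,5}.[VILPTM][VIL][DESTVILMA][VIL].{0,1}[DEST]{1,10}``;
* the murine 8-residue tandem repeat ``GE[PMS]E[ST]EAK``.

Matches are reported non-overlapping, scanning left to right with each match
leftmost-greedy (the discrete "black bar" convention); an overlapping mode
enumerates a match from every possible start position.

Score tracks (e.g. per-residue disorder predictor output) are smoothed with
simple exponential smoothing, s_1 = x_1 and s_t = (1-d) x_t + d s_{t-1},
where d is the damping factor (spreadsheet convention: smoothing constant
alpha = 1 - d).  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.signal import lfilter

from .seqio import ProteinRecord

#: ELM-style SUMO-interacting-motif pattern.
SIM_PATTERN = r"[DEST]{0,5}.[VILPTM][VIL][DESTVILMA][VIL].{0,1}[DEST]{1,10}"

#: The murine GE(P/M/S)E(S/T)EAK tandem repeat unit.
REPEAT_PATTERN = "GE[PMS]E[ST]EAK"


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence, 0-based half-open coordinates."""

    protein_id: str
    pattern_id: str
    start: int
    end: int
    match: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid match interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue real-valued scores for one protein."""

    protein_id: str
    scores: tuple[float, ...]
    smoothed: bool = False
    damping: float | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


def scan_motif(protein: ProteinRecord, pattern: str, pattern_id: str, *,
               overlapping: bool = False) -> list[MotifMatch]:
    """Scan a sequence for a regex motif.

    Default: the maximal non-overlapping match set, scanning left to right
    with each match leftmost-greedy (``re.finditer`` semantics).  With
    ``overlapping=True``, a greedy match is attempted at every start position
    and all distinct intervals are returned.
    """
    rx = re.compile(pattern)
    seq = protein.sequence
    if not overlapping:
        return [
            MotifMatch(protein.id, pattern_id, m.start(), m.end(), m.group())
            for m in rx.finditer(seq)
            if m.end() > m.start()
        ]
    out: list[MotifMatch] = []
    for i in range(len(seq)):
        m = rx.match(seq, i)
        if m is not None and m.end() > m.start():
            out.append(MotifMatch(protein.id, pattern_id, m.start(), m.end(),
                                  m.group()))
    return out


def scan_sim(protein: ProteinRecord, *, overlapping: bool = False
             ) -> list[MotifMatch]:
    """Find SUMO-interacting motifs in a protein sequence."""
    return scan_motif(protein, SIM_PATTERN, "SIM", overlapping=overlapping)


def count_repeat(protein: ProteinRecord, pattern: str = REPEAT_PATTERN) -> int:
    """Count non-overlapping occurrences of a fixed-length degenerate motif."""
    return sum(1 for _ in re.finditer(pattern, protein.sequence))


def smooth(track: ScoreTrack, d: float = 0.9) -> ScoreTrack:
    """Exponentially smooth a score track with damping factor ``d``.

    s_1 = x_1; s_t = (1-d) x_t + d s_{t-1}.  d = 0 returns the input; values
    approaching 1 give ever-heavier smoothing.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError(f"damping factor must lie in [0, 1), got {d}")
    x = track.as_array()
    if x.size == 0:
        raise ValueError("cannot smooth an empty track")
    # IIR filter y[t] = (1-d) x[t] + d y[t-1]; zi makes y[0] = x[0]
    y, _ = lfilter([1.0 - d], [1.0, -d], x, zi=[d * x[0]])
    return replace(track, scores=tuple(float(v) for v in y),
                   smoothed=True, damping=d)


def read_score_track(path: str | Path, protein_id: str | None = None
                     ) -> ScoreTrack:
    """Read a plain-text score track.

    Accepts one numeric score per line, or two whitespace-separated columns
    (position, score) with consecutive integer positions.  Blank lines and
    '#' comment lines are ignored.
    """
    path = Path(path)
    scores: list[float] = []
    positions: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) == 1:
                    scores.append(float(fields[0]))
                elif len(fields) == 2:
                    positions.append(int(fields[0]))
                    scores.append(float(fields[1]))
                else:
                    raise ValueError("expected 1 or 2 columns")
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: cannot parse {line!r} ({err})")
    if not scores:
        raise ValueError(f"{path}: no scores found")
    if positions:
        if len(positions) != len(scores):
            raise ValueError(f"{path}: mixed one- and two-column lines")
        steps = np.diff(positions)
        if positions and (steps != 1).any():
            bad = int(np.argmax(steps != 1))
            raise ValueError(
                f"{path}: positions not consecutive between "
                f"{positions[bad]} and {positions[bad + 1]}"
            )
    return ScoreTrack(protein_id or path.stem, tuple(scores))


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(track.scores, start=1):
            fh.write(f"{i}\t{s:.6g}\n")


def matches_to_rows(matches: Iterable[MotifMatch]) -> list[dict]:
    """Flatten matches to plain dicts (for DataFrame/TSV reporting)."""
    return [
        {"protein": m.protein_id, "pattern": m.pattern_id,
         "start": m.start, "end": m.end, "match": m.match}
        for m in matches
    ]
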