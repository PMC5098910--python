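"""Bundled data files and their loaders.

Everything under ``idrscape/data`` is synthetic: constructed by the package
authors to emulate the statistical character of the real objects, never
measured from external databases.  Filenames carry a ``.synthetic`` marker.
"""

from __future__ import annotations

from importlib import resources

from .seqio import NucleotideRecord, read_fasta


def load_synthetic_gcna_cdna() -> NucleotideRecord:
    """The synthetic stand-in for the mouse Gcna testis cDNA.

    A constructed transcript emulating the documented character of the real
    cloned cDNA: an ATG-initiated open reading frame encoding an acidic,
    heavily repetitive, disordered protein with exactly 25 tandem
    GE(P/M/S)E(S/T)EAK repeat units, SUMO-interacting motifs, and a basic
    NLS-like patch, flanked by short ATG-free 5' and stop-terminated 3'
    untranslated regions.  It is NOT the biological mouse sequence; analyses
    of it exercise the full pipeline with known ground truth.
    """
    ref = resources.files("idrscape").joinpath(
        "data/mouse_gcna_cdna.synthetic.fasta")
    with resources.as_file(ref) as path:
        records = read_fasta(path, alphabet="nucleotide")
    return records[0]
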