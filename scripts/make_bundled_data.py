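"""One-off generation of the bundled synthetic data files (run from repo root)."""
import re
from pathlib import Path

from idrscape.synthetic_data import AMINO_ACIDS, DISORDERED_LIKE, ORDERED_LIKE
from idrscape.seqio import NucleotideRecord, translate_cds
from idrscape.physchem import isoelectric_point
from idrscape.motifs_tracks import count_repeat, scan_sim

DATA = Path("src/idrscape/data")
DATA.mkdir(exist_ok=True)

# --- reference composition tables -----------------------------------------
for tag, prof in [("ordered_like", ORDERED_LIKE), ("disordered_like", DISORDERED_LIKE)]:
    lines = [
        "# Synthetic stand-in residue frequencies emulating the qualitative",
        f"# character of a {tag.replace('_', '-')} protein dataset.",
        "# Package constants; not measurements of any external database.",
    ]
    lines += [f"{aa}\t{prof[aa]:.3f}" for aa in AMINO_ACIDS]
    (DATA / f"{tag}_composition.synthetic.tsv").write_text("\n".join(lines) + "\n")

# --- synthetic mouse-Gcna-like cDNA ----------------------------------------
# Non-repeat regions are S/G/Q/T-rich with sparse D/E and a basic NLS-like
# patch, so that the tandem repeats carry most of the acidity (the character
# documented for the reference object: acidic overall, repeat-dominated).
NTERM = (
    "MDSGRGSSPTAQKLSPNGSQ"
    "SNGSTLQAPKSPGRTQNSGS"
    "KRPAETKKRKLSSGNQGSPT"   # NLS-like basic patch
    "TGNSAPQSQGSTLKNSPVRG"
    "GSNTQGAQSPNKGSTLGNSQ"
)
REPEATS = "".join("GE" + "PMS"[i % 3] + "E" + "ST"[i % 2] + "EAK" for i in range(25))
SIMS = "SGST" + "TSSTAVVIVAT" + "GSPQRSNSG" + "TSSTGPIVLTSST" + "SPAK"
CTERM = (
    "SPGKQNGSTSQNTAQGRSPG"
    "TSQTGSAKNQDSSPANQGLR"
    "GSNAQDSPKQGETSNGQNSA"
    "QNTQGSPGLDNSQGSNYQDK"
)
protein = NTERM + REPEATS + SIMS + CTERM
from collections import Counter
c = Counter(protein)
print("acid/base counts:", {k: c[k] for k in "DEKRH"})

CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "E": "GAA", "Q": "CAA", "G": "GGA", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCA", "T": "ACA", "W": "TGG", "Y": "TAT", "V": "GTT",
}
utr5 = "GCGGCCGCTTCCTGAAC"          # no ATG upstream of the start codon
utr3 = "GACTCCTCGAGTTTAACCCGCT"
cdna = utr5 + "".join(CODON[aa] for aa in protein) + "TAA" + utr3
assert "ATG" not in utr5

rec = NucleotideRecord("synthetic_mouse_gcna", cdna)
prot = translate_cds(rec)
assert prot.sequence == protein, "translation round-trip failed"
n_rep = count_repeat(prot)
assert n_rep == 25, f"repeat count {n_rep} != 25"
pi = isoelectric_point(prot)
sims = scan_sim(prot)
print(f"protein length {len(protein)}, pI {pi:.4f}, repeats {n_rep}, SIMs {len(sims)}")

header = (
    ">synthetic_mouse_gcna SYNTHETIC stand-in transcript emulating the cloned "
    "mouse Gcna testis cDNA: acidic disordered ORF with 25 tandem "
    "GE(P/M/S)E(S/T)EAK repeats, SIMs and an NLS-like patch; not the "
    "biological sequence"
)
wrapped = "\n".join(cdna[i:i + 60] for i in range(0, len(cdna), 60))
(DATA / "mouse_gcna_cdna.synthetic.fasta").write_text(header + "\n" + wrapped + "\n")
print("wrote", DATA / "mouse_gcna_cdna.synthetic.fasta", len(cdna), "nt")
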