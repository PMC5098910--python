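# idrscape

Sequence-level characterization of intrinsically disordered, acidic,
repetitive proteins — the kind of germ-cell nuclear antigens that resist
alignment-based analysis because most of their length is a low-complexity
IDR. For computational biologists studying such protein families,
`idrscape` implements the full desk pipeline:

* **Isoelectric points** from the per-group Henderson–Hasselbalch model
  (`net charge(pH) = Σ_basic 1/(1+10^(pH−pK)) − Σ_acidic 1/(1+10^(pK−pH))`,
  EMBOSS pK set, unique root found by bisection) and acidity percentiles
  against a proteome.
* **Charge–hydropathy (Uversky-plane) classification**: mean scaled
  Kyte–Doolittle hydropathy `<H>` (window 5, scale mapped to [0,1]) against
  absolute mean net charge `<R>` (net charge at pH 7 / length); a chain is
  disordered iff `<H> < (<R> + 1.151)/2.785`.
* **Composition enrichment** `(C_x − C_order)/C_order` with residue-level
  bootstrap error bars.
* **Motif scanning**: the ELM-style SUMO-interacting-motif pattern
  `[DEST]{0,5}.[VILPTM][VIL][DESTVILMA][VIL].{0,1}[DEST]{1,10}` and
  tandem-repeat counting (default unit `GE[PMS]E[ST]EAK`).
* **Disorder-track smoothing** (`s_t = (1−d)x_t + d·s_{t−1}`, damping 0.9).
* **Ortholog triage** from per-domain profile-HMM hit tables: strict
  E < 1e-5 significance, longest-isoform and one-strain-per-species rules,
  full (protease + zinc finger + HMG box) vs partial (protease + zinc
  finger) architecture calls.
* **HMM-similarity clustering**: `D = −ln max(p, 0.001)` from HMM–HMM match
  probabilities, average-linkage dendrograms, Newick export.

cDNA translation, FASTA I/O, and seeded synthetic-data generators with
ground truth for every input class round out the package. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

The package bundles a *synthetic* stand-in transcript
(`mouse_gcna_cdna.synthetic.fasta`) constructed to emulate the character of
a cloned germ-cell antigen cDNA — an acidic, repeat-dominated ORF with 25
tandem GE(P/M/S)E(S/T)EAK units and SUMO-interacting motifs:

```python
from idrscape.data import load_synthetic_gcna_cdna
from idrscape.seqio import translate_cds
from idrscape.physchem import isoelectric_point
from idrscape.ch_plane import ch_point
from idrscape.motifs_tracks import count_repeat, scan_sim

prot = translate_cds(load_synthetic_gcna_cdna())
print("protein length:", len(prot))
print("pI:", round(isoelectric_point(prot), 2))
p = ch_point(prot)
print(f"<H> = {p.H:.3f}, <R> = {p.R:.3f}, call = {p.call}")
print("repeats:", count_repeat(prot))
for m in scan_sim(prot):
    print("SIM", m.start, m.end, m.match)
```

prints

```
protein length: 421
pI: 4.2
<H> = 0.335, <R> = 0.085, call = disordered
repeats: 25
SIM 303 315 TTSSTAVVIVAT
SIM 324 338 TSSTGPIVLTSSTS
```

— a strongly acidic protein (pI 4.20; at pH 7 it carries about −36 e over
421 residues), landing deep on the disordered side of the
charge–hydropathy boundary (`<H>` = 0.335 against a boundary of 0.444 at
that `<R>`), with its 25 repeat units and two SIMs recovered at their
planted coordinates.

The same stages are available from a shell:

```sh
idrscape translate --in cdna.fa --out protein.fa
idrscape pi --in protein.fa --out pi.tsv
idrscape chplot --in idrs.fa --out ch.tsv --plot ch.svg
idrscape composition --query idrs.fa --reference ordered_like --out enr.tsv
idrscape sim-scan --in protein.fa --out sims.tsv
idrscape repeat-count --in protein.fa --out repeats.tsv
idrscape smooth --in disorder_scores.txt --damping 0.9 --out smoothed.tsv
idrscape triage --hits hits.tsv --threshold 1e-5 --out calls.tsv
idrscape hmm-cluster --probs matrix.tsv --out tree.nwk
idrscape synth --spec spec.json --out synth_dir/
```

Every command writes a JSON manifest (parameters, version, input digests)
next to its output; reruns with the same configuration are byte-identical.

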