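# nr2dbd

Annotation, classification and nomenclature for **nuclear receptors with
two DNA-binding domains (2DBD-NRs)** — an atypical receptor family with
the modular layout A/B–DBD–DBD–hinge–LBD found across protostomes and
deuterostomes (platyhelminths, rotifers, molluscs, annelids,
echinoderms, nematodes, …).

The package is aimed at molecular parasitologists and comparative
endocrinologists who have candidate protein sequences (e.g. from genome
mining) and want to ask: *is this a 2DBD-NR, which group does it belong
to, and what should it be called?*

## The motif grammar

Everything rests on a small set of degenerate sequence signatures:

* **C4 zinc fingers.** Each DBD is CI + CII with fixed anchor spacings
  C-X2-C-X13-C-X2-C (CI) and C-X5-C-X9-C-X2-C (CII). The atypical
  CHC2 finger (C-X6-C-X9-H-X2-C) is scanned as a negative control — it
  never occurs in 2DBD-NRs.
* **P-box** — the 5 residues after CI's third cysteine (its middle
  letter is CI's fourth cysteine); **D-box** — the 5 residues of CII's
  C-X5-C.
* **P-P module** — the ordered pair of P-boxes of the two DBDs, e.g.
  `CEACKK-CEGCKG`. Four signatures are group-diagnostic
  (A: `CEACKK-CEGCKG`, `CEACKK-CEACKG`; B: `CLPCKS-CEGCKK`,
  `CEACKS-CEGCKG`); group C (Nematoda) is highly variable and is gated
  by taxon.
* **Linker** — 2DBD-NRs carry 17–22 residues between the two DBDs.
* **CTE / G-box** — Grip box RXGRZP (X ∈ {F,R,G}, Z hydrophobic) with
  group variants RXGRQ(P/S) (A), KXGR(P/H) (B) and RDRRGP (C); the
  pre-Grip stretch is 5 residues in A/B and 8 in C, so no 12-residue
  T-box fits; a conserved H sits five residues after the G-box in most
  group-A members.
* **LBD** — detected through the 20-residue Ti signature
  `(F,W,Y)(A,S,I)(K,R,E,G)xxxx(F,L)xx(L,V,I)xxx(D,S)(Q,K)xx(L,V)(L,I,F)`;
  the AF2-AD core ΦΦxEΦΦ has group variants ΦΦx(E,Q,R)ΦΦ (A),
  ΦΦx(E,K)Φh (B) and xxΦΦΦΦ (*C. brenneri* C). Dimerization class uses
  the Brelivet marker residues (class I: E5, E50, KR55, RK93; class II:
  ED42, E50, R62, HRK90); 2DBD-NRs show the class I profile with KR55
  absent.
* **NTSS** — clade-specific N-terminal signatures of parasitic
  platyhelminth 2DBD-NRs (`CNLGXKDRRP`, `TNDVTAMKEKTP`,
  `(S/T)PEXAFXQYQXR(M/S)EGQX`).

A rule-based classifier maps the P-P module to groups A/B/C and a
neighbor-joining tree over pairwise-aligned DBD regions (BLOSUM62,
affine gaps) corroborates the split. Names follow the proposed
nomenclature `<species code>2DBD-NR<group><gene>[<variant>]`, e.g.
`Bc2DBD-NRA1a`.

## Worked example

The built-in generator emits synthetic panels with ground truth — five
two-DBD templates covering every P-P situation plus four decoys:

```sh
nr2dbd simulate -n 1 --seed 5 --out-fasta panel.fasta
printf 'C1_000\tNematoda\n' > taxa.tsv
nr2dbd scan panel.fasta -o scan.tsv --taxon-map taxa.tsv
```

`scan.tsv` (columns abridged):

```
seq_id       architecture  linker_len  pp_module       group  gbox    pre_grip_len  tbox_present  af2
A1_000       TWO_DBD_NR    22          CEACKK-CEGCKG   A      RFGRQP  5             false         LLDELL
A2_000       TWO_DBD_NR    20          CEACKK-CEACKG   A      RFGRQP  5             false         LLDELL
B1_000       TWO_DBD_NR    20          CLPCKS-CEGCKK   B      KSGRP   5             false         IVTKVR
B2_000       TWO_DBD_NR    19          CEACKS-CEGCKG   B      KSGRP   5             false         IVTKVR
C1_000       TWO_DBD_NR    19          CKGCNV-CDSCRT   C      RDRRGP  8             false
typical_000  TYPICAL_NR                                       RFGRLP  5             false         LLGELL
lbdonly_000  LBD_ONLY
random_000   NOT_NR
chc2_000     NOT_NR
```

Reading the rows: all five positives are recognized as two-DBD
receptors with linkers inside 17–22; the four exact P-P signatures hit
at distance 0; the nematode-style C1 carries the RDRRGP G-box behind an
8-residue pre-Grip (A/B show 5), so `tbox_present` is false everywhere —
there is no conserved T-box in 2DBD-NRs. The group-C member has a Ti
signature but no AF2, as in *Aphelenchus avenae*. Decoys never classify
as TWO_DBD_NR.

`nr2dbd tree panel.fasta -o tree.nwk` writes the NJ corroborator,
`nr2dbd name scan.tsv --species-map sp.tsv -o names.tsv` assigns
nomenclature names, and `nr2dbd config -o config.yaml` exports every
motif table and tolerance to a single editable file.

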