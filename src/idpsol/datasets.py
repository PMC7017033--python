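"""Reference sequences of well-characterized amyloidogenic IDPs.

Small, public, canonical sequences used in examples and tests.  All are
represented with free termini and unmodified cysteines; where the mature
peptide is chemically modified in vivo (IAPP is C-terminally amidated
and disulfide-bonded), the plain sequence is kept here and the modified
construct can be derived via the terminal-blocking flags.
"""

from __future__ import annotations

from .sequence_io import ProteinSequence

__all__ = ["ALPHA_SYNUCLEIN", "ABETA40", "IAPP", "reference_sequences"]

#: Human α-synuclein (UniProt P37840), 140 residues.
ALPHA_SYNUCLEIN = ProteinSequence(
    id="alpha_synuclein_P37840",
    residues=(
        "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
        "EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
        "DNEAYEMPSEEGYQDYEPEA"
    ),
)

#: Amyloid-β 1–40, residues 672–711 of human APP (UniProt P05067).
ABETA40 = ProteinSequence(
    id="abeta40_P05067_672_711",
    residues="DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV",
)

#: Mature human islet amyloid polypeptide (amylin), 37 residues
#: (UniProt P10997 34–70), plain chain.
IAPP = ProteinSequence(
    id="iapp_P10997_mature",
    residues="KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY",
)


def reference_sequences() -> list[ProteinSequence]:
    return [ALPHA_SYNUCLEIN, ABETA40, IAPP]
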