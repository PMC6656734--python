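"""Canonical mitochondrial gene vocabulary.

The metazoan mitogenome carries 37 genes: 13 protein-coding genes (PCGs),
2 ribosomal RNAs and 22 tRNAs (leucine and serine each have two isoacceptor
genes, disambiguated by anticodon family). Everything in the package speaks
in these normalised tokens.
"""

from __future__ import annotations

PCG_TOKENS: frozenset[str] = frozenset(
    {
        "atp6",
        "atp8",
        "cob",
        "cox1",
        "cox2",
        "cox3",
        "nad1",
        "nad2",
        "nad3",
        "nad4",
        "nad4l",
        "nad5",
        "nad6",
    }
)

RRNA_TOKENS: frozenset[str] = frozenset({"rrnS", "rrnL"})

_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

TRNA_TOKENS: frozenset[str] = frozenset(
    {f"trn{aa}" for aa in _AA_LETTERS if aa not in "LS"}
    | {"trnL1", "trnL2", "trnS1", "trnS2"}
)

ALL_TOKENS: frozenset[str] = PCG_TOKENS | RRNA_TOKENS | TRNA_TOKENS

#: sentinel for labels the normaliser cannot resolve
UNKNOWN = "unknown"

#: amino-acid three-letter -> one-letter map used when parsing tRNA names
AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

#: anticodon (DNA alphabet, lower case) -> isoacceptor index for Leu/Ser
LEU_SER_ANTICODONS = {
    ("L", "tag"): "trnL1",  # Leu(CUN)
    ("L", "taa"): "trnL2",  # Leu(UUR)
    ("S", "tct"): "trnS1",  # Ser(AGN)
    ("S", "gct"): "trnS1",
    ("S", "tga"): "trnS2",  # Ser(UCN)
}


def classify_token(token: str) -> str:
    """Return the gene class of a normalised token: PCG, rRNA, tRNA or other."""
    if token in PCG_TOKENS:
        return "PCG"
    if token in RRNA_TOKENS:
        return "rRNA"
    if token in TRNA_TOKENS:
        return "tRNA"
    return "other"
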