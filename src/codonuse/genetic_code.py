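"""Standard genetic code structures shared by every statistic in the package.

The bacterial/plastid translation table (NCBI transl_table 11) is used; its
codon-to-amino-acid assignments coincide with the standard code: 61 sense
codons, stop codons TAA/TAG/TGA, and exactly two single-codon families,
Met (ATG) and Trp (TGG).  Synonymous families are grouped by amino acid;
their sizes (degeneracies) here are 1, 2, 3, 4 or 6, with Leu, Ser and Arg
treated as undivided six-fold families.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[11]

BASES = "ACGT"

#: All 64 codons in lexicographic order; every count vector is indexed by this.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: codon -> one-letter amino acid; stop codons map to "*".
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in CODONS if c not in STOP_CODONS}
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

_fam: dict[str, list[str]] = {}
for _c in CODONS:
    _fam.setdefault(CODON_TO_AA[_c], []).append(_c)

#: amino acid (or "*") -> tuple of its codons, lexicographically ordered.
FAMILIES: dict[str, tuple[str, ...]] = {aa: tuple(sorted(cs)) for aa, cs in _fam.items()}

#: amino acid -> family size (degeneracy); "*" maps to 3.
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in FAMILIES.items()}

#: The two amino acids encoded by a single codon (Met, Trp).
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, k in DEGENERACY.items() if k == 1 and aa != "*"
)

#: Degeneracy class -> amino acids, for Wright's ENc decomposition:
#: nine two-fold, one three-fold (Ile), five four-fold, three six-fold
#: (Leu, Ser, Arg).  Met, Trp and stops carry no synonymous information.
ENC_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _k in sorted(DEGENERACY.items()):
    if _aa == "*" or _k < 2:
        continue
    ENC_CLASSES.setdefault(_k, ())
    ENC_CLASSES[_k] = ENC_CLASSES[_k] + (_aa,)

#: The 59 sense codons carrying synonymous-choice information
#: (ATG, TGG and the stop codons removed); the coordinate system for
#: per-gene RSCU vectors in correspondence analysis and genome clustering.
COA_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

assert len(CODONS) == 64 and len(SENSE_CODONS) == 61 and len(COA_CODONS) == 59
assert {k: len(v) for k, v in ENC_CLASSES.items()} == {2: 9, 3: 1, 4: 5, 6: 3}
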