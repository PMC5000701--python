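"""Reading coding sequences, inclusion filtering and codon counting.

CDS sets come in as multi-FASTA (NCBI CDS-extraction header dialect
tolerated) or GenBank flat files.  Before any codon-usage statistic is
computed, sequences pass an inclusion filter modelled on the usual
genome-scale practice: at least 100 codons, a correct initiation codon,
a clean reading frame and no internal stop.  Each rejected CDS is charged
to the first rule it fails so the filter report is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .genetic_code import CODON_INDEX, CODONS, STOP_CODONS

_GENE_RE = re.compile(r"\[gene=([^\]]+)\]")
_PRODUCT_RE = re.compile(r"\[protein=([^\]]+)\]")
_LOCUS_RE = re.compile(r"\[locus_tag=([^\]]+)\]")


@dataclass
class CodingSequence:
    """One CDS: nucleotide sequence plus minimal annotation.

    The sequence is stored uppercased with U normalised to T.
    """

    gene_id: str
    genome_id: str
    seq: str
    gene: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.gene_id!r}")

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3


_REJECT_RULES = ("too_short", "bad_start", "bad_frame", "internal_stop", "ambiguous")


@dataclass
class CdsFilterReport:
    """Per-rule rejection tallies; n_input == n_passing + sum(rejections)."""

    n_input: int = 0
    n_passing: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in _REJECT_RULES}
    )

    def check(self) -> bool:
        return self.n_input == self.n_passing + sum(self.rejections.values())


def _parse_header(record) -> tuple[str, str | None, str | None]:
    desc = record.description
    gene = m.group(1) if (m := _GENE_RE.search(desc)) else None
    product = m.group(1) if (m := _PRODUCT_RE.search(desc)) else None
    gene_id = record.id
    if (m := _LOCUS_RE.search(desc)) and gene_id.startswith("lcl|"):
        gene_id = m.group(1)
    return gene_id, gene, product


def read_cds_fasta(path: str | Path, genome_id: str | None = None) -> list[CodingSequence]:
    """Read a multi-FASTA of CDS into :class:`CodingSequence` records.

    ``genome_id`` defaults to the file stem.  NCBI CDS headers
    (``[gene=...]``, ``[protein=...]``) are parsed when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gid = genome_id if genome_id is not None else path.stem
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, gene, product = _parse_header(rec)
        out.append(CodingSequence(gene_id, gid, str(rec.seq), gene=gene, product=product))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def read_cds_genbank(path: str | Path, genome_id: str | None = None) -> list[CodingSequence]:
    """Extract CDS features from a GenBank flat file.

    Feature locations are honoured (join() pieces concatenated, complement
    strands reverse-complemented) via Biopython's feature extraction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gid = genome_id if genome_id is not None else path.stem
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = quals.get("locus_tag", quals.get("protein_id", [None]))[0]
            if gene_id is None:
                gene_id = f"{rec.id}_cds_{len(out) + 1}"
            out.append(
                CodingSequence(
                    gene_id,
                    gid,
                    str(feat.extract(rec.seq)),
                    gene=quals.get("gene", [None])[0],
                    product=quals.get("product", [None])[0],
                )
            )
    if not out:
        raise ValueError(f"no CDS features found in {path}")
    return out


def filter_cds(
    seqs: Iterable[CodingSequence],
    min_codons: int = 100,
    start_codons: Sequence[str] | frozenset[str] = ("ATG",),
    require_clean_frame: bool = True,
    max_ambiguous_frac: float = 0.05,
) -> tuple[list[CodingSequence], CdsFilterReport]:
    """Apply the CDS inclusion rules; each CDS is charged to its first failure.

    Rule order: too short -> bad start -> frame violation -> internal stop ->
    excess ambiguous triplets.  A terminal stop codon is allowed (and later
    counted); stops at any earlier in-frame position reject the CDS.
    """
    starts = frozenset(start_codons)
    report = CdsFilterReport()
    kept: list[CodingSequence] = []
    for s in seqs:
        report.n_input += 1
        seq = s.seq
        if len(seq) < 3 * min_codons:
            report.rejections["too_short"] += 1
            continue
        if seq[:3] not in starts:
            report.rejections["bad_start"] += 1
            continue
        if require_clean_frame and len(seq) % 3 != 0:
            report.rejections["bad_frame"] += 1
            continue
        n_full = len(seq) // 3
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            report.rejections["internal_stop"] += 1
            continue
        n_ambig = sum(1 for c in codons if not set(c) <= set("ACGT"))
        if n_full and n_ambig / n_full > max_ambiguous_frac:
            report.rejections["ambiguous"] += 1
            continue
        report.n_passing += 1
        kept.append(s)
    return kept, report


@dataclass
class CodonCountTable:
    """64 codon counts for a gene or a pooled gene set.

    ``counts`` is indexed by :data:`codonuse.genetic_code.CODONS`.  Triplets
    containing ambiguous bases are never counted.
    """

    label: str
    counts: np.ndarray  # shape (64,), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (self.counts < 0).any():
            raise ValueError("negative codon count")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int], label: str = "") -> "CodonCountTable":
        counts = np.zeros(64, dtype=np.int64)
        for codon, n in mapping.items():
            counts[CODON_INDEX[codon.upper().replace("U", "T")]] = n
        return cls(label, counts)

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.counts) if n}


def count_codons(seq: CodingSequence | str, label: str | None = None) -> CodonCountTable:
    """Tally in-frame codons of a CDS; N-containing triplets are skipped.

    The terminal stop codon, when present, is included in the table; each
    downstream statistic decides whether stops participate.
    """
    if isinstance(seq, CodingSequence):
        s, lab = seq.seq, seq.gene_id
    else:
        s, lab = seq.upper().replace("U", "T"), label or ""
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} not a multiple of 3 ({lab!r})")
    counts = np.zeros(64, dtype=np.int64)
    for i in range(0, len(s), 3):
        idx = CODON_INDEX.get(s[i : i + 3])
        if idx is not None:
            counts[idx] += 1
    return CodonCountTable(label if label is not None else lab, counts)


def pool_counts(tables: Sequence[CodonCountTable], label: str) -> CodonCountTable:
    """Elementwise sum of count tables (e.g. genome-level pooled usage)."""
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    total = np.zeros(64, dtype=np.int64)
    for t in tables:
        total += t.counts
    return CodonCountTable(label, total)


def write_counts_tsv(tables: Sequence[CodonCountTable], path: str | Path) -> None:
    """Write count tables as TSV: one row per gene, 64 codon columns + total."""
    import pandas as pd

    df = pd.DataFrame(
        [t.counts for t in tables], index=[t.label for t in tables], columns=list(CODONS)
    )
    df["total"] = df.sum(axis=1)
    df.to_csv(path, sep="\t", index_label="gene_id")
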