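"""Highly expressed gene prediction from CAI.

The CAI reference set is the genome's own ribosomal proteins, recognised
from annotations ("ribosomal protein" products or rpl*/rps*/rpm* gene
symbols) or supplied as an explicit list.  Within each genome the top 5%
of genes by CAI are predicted highly expressed; predictions are compared
across genomes by shared gene symbol (annotation-keyed orthology).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import CodingSequence

_PRODUCT_PATTERN = re.compile(r"ribosomal\s+protein", re.IGNORECASE)
_SYMBOL_PATTERN = re.compile(r"^rp[lsm]\w*$", re.IGNORECASE)


@dataclass
class ReferenceSelection:
    """Ribosomal-protein reference genes plus how each one matched."""

    sequences: list[CodingSequence]
    provenance: dict[str, str] = field(default_factory=dict)  # gene_id -> rule


def select_reference(genes: Sequence[CodingSequence]) -> ReferenceSelection:
    """Pick ribosomal-protein genes by annotation pattern.

    Matches case-insensitive "ribosomal protein" in the product string or a
    gene symbol starting rpl/rps/rpm.  Raises when nothing matches so the
    caller can fall back to an explicit reference list file.
    """
    selected: list[CodingSequence] = []
    prov: dict[str, str] = {}
    for g in genes:
        if g.gene and _SYMBOL_PATTERN.match(g.gene):
            selected.append(g)
            prov[g.gene_id] = f"gene symbol {g.gene!r}"
        elif g.product and _PRODUCT_PATTERN.search(g.product):
            selected.append(g)
            prov[g.gene_id] = "product matches 'ribosomal protein'"
    if not selected:
        raise ValueError(
            "no ribosomal-protein genes found by annotation; supply a reference "
            "list file (one gene id or symbol per line) via load_reference_list()"
        )
    return ReferenceSelection(selected, prov)


def load_reference_list(path: str | Path, genes: Sequence[CodingSequence]) -> ReferenceSelection:
    """Select reference genes named (by id or symbol) in a plain-text file."""
    wanted = {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    selected = [g for g in genes if g.gene_id in wanted or (g.gene and g.gene in wanted)]
    if not selected:
        raise ValueError(f"no genes matched the reference list {path}")
    return ReferenceSelection(selected, {g.gene_id: "listed in reference file" for g in selected})


@dataclass
class ExpressionPrediction:
    """Top-fraction-by-CAI prediction of highly expressed genes in one genome."""

    genome_id: str
    cai: pd.Series  # per-gene CAI, indexed by gene id
    cutoff: float
    predicted: tuple[str, ...]
    reference_ids: tuple[str, ...] = ()
    fraction: float = 0.05


def predict_highly_expressed(
    cai: pd.Series | Mapping[str, float],
    fraction: float = 0.05,
    genome_id: str = "",
    reference_ids: Iterable[str] = (),
) -> ExpressionPrediction:
    """Predict the top ``ceil(fraction * n)`` genes by CAI as highly expressed.

    The cutoff is the smallest CAI among the selected genes; ties break by
    gene id so the prediction is deterministic.
    """
    s = pd.Series(cai, dtype=float).dropna()
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_top = math.ceil(fraction * len(s))
    if len(s) == 0 or n_top < 1:
        raise ValueError(f"too few genes ({len(s)}) for a top-{fraction:.0%} prediction")
    order = s.sort_index().sort_values(ascending=False, kind="stable")
    top = order.iloc[:n_top]
    return ExpressionPrediction(
        genome_id=genome_id,
        cai=s,
        cutoff=float(top.min()),
        predicted=tuple(top.index),
        reference_ids=tuple(reference_ids),
        fraction=fraction,
    )


@dataclass
class OrthologSharingReport:
    """Cross-genome intersection of predicted highly expressed gene symbols."""

    shared_all: frozenset[str]
    by_symbol: dict[str, tuple[str, ...]]  # symbol -> genomes predicting it
    unnamed: dict[str, tuple[str, ...]]  # genome -> predicted gene ids without symbol

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "symbol": sym,
                "n_genomes": len(genomes),
                "in_all": sym in self.shared_all,
                "genomes": ",".join(genomes),
            }
            for sym, genomes in sorted(self.by_symbol.items())
        ]
        return pd.DataFrame(rows, columns=["symbol", "n_genomes", "in_all", "genomes"])


def shared_orthologs(
    predictions: Sequence[ExpressionPrediction],
    symbol_map: Mapping[str, str],
) -> OrthologSharingReport:
    """Partition predicted gene symbols by the set of genomes sharing them.

    ``symbol_map`` maps gene id to gene symbol; predicted genes without a
    symbol are reported per genome as unnamed (hypothetical) candidates.
    """
    if len(predictions) < 2:
        raise ValueError("need predictions from at least 2 genomes")
    by_symbol: dict[str, list[str]] = {}
    unnamed: dict[str, tuple[str, ...]] = {}
    for pred in predictions:
        symbols = set()
        missing = []
        for gid in pred.predicted:
            sym = symbol_map.get(gid)
            if sym:
                symbols.add(sym)
            else:
                missing.append(gid)
        for sym in symbols:
            by_symbol.setdefault(sym, []).append(pred.genome_id)
        unnamed[pred.genome_id] = tuple(missing)
    all_genomes = {p.genome_id for p in predictions}
    shared_all = frozenset(
        sym for sym, genomes in by_symbol.items() if set(genomes) == all_genomes
    )
    return OrthologSharingReport(
        shared_all,
        {sym: tuple(sorted(set(g))) for sym, g in by_symbol.items()},
        unnamed,
    )
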