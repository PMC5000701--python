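"""Per-gene and pooled codon-usage statistics.

Implements the classic battery of codon bias indices for a codon count
table:

* RSCU — relative synonymous codon usage, the observed count of a codon
  divided by its expected count under equal use within the synonymous
  family; values > 1 mark preferred codons.
* Positional GC partitions — GC, P1/P2/P3 (after excluding ATG, TGG, ATA
  and the stop codons), P12 = (P1+P2)/2, and GC3s (third-position GC over
  sense codons excluding Met, Trp and stops; ATA is retained because Ile
  is synonymous).
* ENc — Wright's effective number of codons, built from per-family
  homozygosity estimates averaged within degeneracy classes
  (nine 2-fold, Ile as the sole 3-fold, five 4-fold, Leu/Ser/Arg as
  6-fold), capped to [20, 61].
* The expected-ENc curve under pure GC3s-driven usage,
  ``2 + s + 29/(s^2 + (1-s)^2)``.
* CAI — codon adaptation index of Sharp & Li: the geometric mean of
  relative-adaptiveness weights derived from a highly expressed reference
  set (here, ribosomal proteins).
* Optimal codon detection — per-codon 2x2 chi-squared contrasts between a
  high-bias and a low-bias gene group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    COA_CODONS,
    DEGENERACY,
    ENC_CLASSES,
    FAMILIES,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    STOP_CODONS,
)
from .sequence_io import CodonCountTable

# ---------------------------------------------------------------------------
# RSCU

def rscu(counts: CodonCountTable, include_stops: bool = True) -> pd.Series:
    """Relative synonymous codon usage per codon.

    For codon ``c`` in a family of size ``k`` with family total ``N > 0``:
    ``RSCU(c) = count(c) / (N / k)``.  Families never observed yield NaN
    (missing, not zero).  Stop codons form a 3-member family when
    ``include_stops`` is true.
    """
    families = FAMILIES if include_stops else {a: f for a, f in FAMILIES.items() if a != "*"}
    values: dict[str, float] = {}
    for aa, codons in families.items():
        k = len(codons)
        n = sum(counts[c] for c in codons)
        for c in codons:
            values[c] = counts[c] * k / n if n > 0 else math.nan
    order = [c for c in CODONS if c in values]
    return pd.Series([values[c] for c in order], index=order, name=counts.label or "rscu")


def preferred_codons(rscu_values: pd.Series) -> set[str]:
    """Codons with RSCU strictly greater than 1 (positive usage bias)."""
    return set(rscu_values.index[rscu_values > 1.0])


# ---------------------------------------------------------------------------
# GC partitions

_P123_EXCLUDE = frozenset({"ATG", "TGG", "ATA"}) | STOP_CODONS
_GC3S_EXCLUDE = frozenset({"ATG", "TGG"}) | STOP_CODONS

_IS_GC = np.array([[b in "GC" for b in codon] for codon in CODONS], dtype=float)
_P123_MASK = np.array([c not in _P123_EXCLUDE for c in CODONS], dtype=float)
_GC3S_MASK = np.array([c not in _GC3S_EXCLUDE for c in CODONS], dtype=float)


@dataclass
class GcPartition:
    """Positional GC fractions of one count table; NaN when undefined."""

    gc: float
    p1: float
    p2: float
    p3: float
    p12: float
    gc3s: float


def gc_partition(counts: CodonCountTable) -> GcPartition:
    """GC, P1/P2/P3, P12 and GC3s under the standard codon exclusions.

    P1/P2/P3 drop ATG, TGG, ATA and stops; GC3s drops ATG, TGG and stops
    (ATA kept — Ile has synonymous choice); GC runs over every position of
    every counted codon.
    """
    n = counts.counts.astype(float)
    total = n.sum()
    gc = float((n @ _IS_GC).sum() / (3 * total)) if total else math.nan

    npos = n * _P123_MASK
    denom = npos.sum()
    if denom:
        p1, p2, p3 = (npos @ _IS_GC) / denom
        p1, p2, p3 = float(p1), float(p2), float(p3)
    else:
        p1 = p2 = p3 = math.nan

    n3 = n * _GC3S_MASK
    d3 = n3.sum()
    gc3s = float((n3 @ _IS_GC[:, 2]) / d3) if d3 else math.nan

    return GcPartition(gc=gc, p1=p1, p2=p2, p3=p3, p12=(p1 + p2) / 2, gc3s=gc3s)


# ---------------------------------------------------------------------------
# ENc

@dataclass
class EncValue:
    """Wright's effective number of codons for one gene (or pool)."""

    enc: float
    f_by_class: dict[int, float] = field(default_factory=dict)
    n_families: int = 0
    note: str = ""


def _family_homozygosity(counts: CodonCountTable, codons: Sequence[str]) -> float | None:
    """F-hat = (n * sum p_i^2 - 1) / (n - 1); None when unscorable (n < 2)."""
    ns = np.array([counts[c] for c in codons], dtype=float)
    n = ns.sum()
    if n < 2:
        return None
    p = ns / n
    f = (n * float(p @ p) - 1.0) / (n - 1.0)
    return f


def enc(counts: CodonCountTable) -> EncValue:
    """Wright's ENc with the 9/1/5/3 degeneracy-class decomposition.

    Class means of family homozygosity F-hat feed
    ``ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.  Families with fewer than two
    observations (or F-hat = 0) are unscorable.  A missing Ile class is
    imputed as (F2+F4)/2; any other missing class falls back to the mean of
    the available class means.  The estimate is capped to [20, 61].
    """
    fbar: dict[int, float] = {}
    n_fam = 0
    for k, aas in ENC_CLASSES.items():
        fs = []
        for aa in aas:
            f = _family_homozygosity(counts, FAMILIES[aa])
            if f is not None and f > 0:
                fs.append(f)
        if fs:
            fbar[k] = float(np.mean(fs))
            n_fam += len(fs)
    if not fbar or 2 not in fbar:
        return EncValue(math.nan, fbar, n_fam, note="no scorable two-fold family")
    note = ""
    if 3 not in fbar:
        if 4 in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2.0
            note = "F3 imputed from (F2+F4)/2"
        else:
            fbar[3] = fbar[2]
            note = "F3 imputed from F2"
    for k in (4, 6):
        if k not in fbar:
            fbar[k] = float(np.mean([v for kk, v in fbar.items() if kk != k]))
            note = (note + "; " if note else "") + f"F{k} imputed from class mean"
    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    value = min(max(value, 20.0), 61.0)
    return EncValue(value, fbar, n_fam, note=note)


def expected_enc(s) -> float | np.ndarray:
    """Expected ENc under purely GC3s-driven codon usage.

    ``ENc*(s) = 2 + s + 29 / (s^2 + (1-s)^2)`` for GC3s fraction ``s``.
    Accepts a scalar or array in [0, 1].
    """
    arr = np.asarray(s, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("GC3s must lie in [0, 1]")
    out = 2.0 + arr + 29.0 / (arr**2 + (1.0 - arr) ** 2)
    return float(out) if np.ndim(s) == 0 else out


# ---------------------------------------------------------------------------
# CAI

#: sense codons scored by CAI (Met, Trp and stops never contribute)
CAI_CODONS: tuple[str, ...] = COA_CODONS


@dataclass
class CaiModel:
    """Relative-adaptiveness weights w per scored codon; max w = 1 per family."""

    weights: pd.Series
    reference_label: str = "reference"
    floored: frozenset[str] = frozenset()
    absent_families: frozenset[str] = frozenset()


def cai_weights(reference: Sequence[CodonCountTable], label: str = "reference") -> CaiModel:
    """Build CAI weights from a pooled reference set (Sharp & Li).

    ``w(c) = count(c) / max count in family``.  Zero-count codons in an
    observed family get a floor of ``0.5 / max count``; families absent from
    the reference altogether are neutral (w = 1 for every member) and
    flagged.  Met, Trp and stop codons are never scored.
    """
    if not reference:
        raise ValueError("empty CAI reference set")
    pooled = np.zeros(64, dtype=np.int64)
    for t in reference:
        pooled += t.counts
    weights: dict[str, float] = {}
    floored: set[str] = set()
    absent: set[str] = set()
    for aa, codons in FAMILIES.items():
        if aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        ns = {c: int(pooled[CODON_INDEX[c]]) for c in codons}
        mx = max(ns.values())
        if mx == 0:
            absent.add(aa)
            for c in codons:
                weights[c] = 1.0
                floored.add(c)
            continue
        for c, n in ns.items():
            if n == 0:
                weights[c] = 0.5 / mx
                floored.add(c)
            else:
                weights[c] = n / mx
    w = pd.Series([weights[c] for c in CAI_CODONS], index=list(CAI_CODONS), name="w")
    return CaiModel(w, label, frozenset(floored), frozenset(absent))


def cai(counts: CodonCountTable, model: CaiModel) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Met, Trp and stop codons are excluded.  NaN when the gene has no scored
    codon.
    """
    n = np.array([counts[c] for c in CAI_CODONS], dtype=float)
    total = n.sum()
    if total == 0:
        return math.nan
    logw = np.log(model.weights.to_numpy())
    return float(math.exp((n @ logw) / total))


# ---------------------------------------------------------------------------
# Optimal codons

@dataclass
class OptimalCodonResult:
    """Per-codon chi-squared contrast between high- and low-bias gene groups."""

    table: pd.DataFrame  # columns: aa, chi2, pvalue, enriched_high, optimal, skipped
    alpha: float
    meta: str = "2x2 chi-squared, no continuity correction, two-sided"

    @property
    def optimal_set(self) -> set[str]:
        return set(self.table.index[self.table["optimal"]])


def optimal_codons(
    high_group: Sequence[CodonCountTable],
    low_group: Sequence[CodonCountTable],
    alpha: float = 0.01,
) -> OptimalCodonResult:
    """Flag codons significantly enriched in the high-bias group.

    For each codon of a multi-codon family, a 2x2 table (codon count vs
    rest-of-family count, high vs low group) is tested by chi-squared
    without continuity correction; codons with p < alpha and higher relative
    family usage in the high group are optimal.  Degenerate tables (a zero
    margin) are skipped and flagged.
    """
    if not high_group or not low_group:
        raise ValueError("both gene groups must be non-empty")
    hi = np.zeros(64, dtype=np.int64)
    lo = np.zeros(64, dtype=np.int64)
    for t in high_group:
        hi += t.counts
    for t in low_group:
        lo += t.counts
    rows = []
    for aa, codons in FAMILIES.items():
        if aa == "*" or len(codons) < 2:
            continue
        fam_hi = sum(int(hi[CODON_INDEX[c]]) for c in codons)
        fam_lo = sum(int(lo[CODON_INDEX[c]]) for c in codons)
        for c in codons:
            a, b = int(hi[CODON_INDEX[c]]), fam_hi - int(hi[CODON_INDEX[c]])
            d, e = int(lo[CODON_INDEX[c]]), fam_lo - int(lo[CODON_INDEX[c]])
            tab = np.array([[a, b], [d, e]])
            if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
                rows.append((c, aa, math.nan, math.nan, False, False, True))
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            enriched = a / fam_hi > d / fam_lo
            rows.append((c, aa, float(chi2), float(p), enriched, p < alpha and enriched, False))
    df = pd.DataFrame(
        rows, columns=["codon", "aa", "chi2", "pvalue", "enriched_high", "optimal", "skipped"]
    ).set_index("codon")
    return OptimalCodonResult(df, alpha)


# ---------------------------------------------------------------------------
# Per-gene metrics table

def gene_metrics_table(
    tables: Sequence[CodonCountTable], cai_model: CaiModel | None = None
) -> pd.DataFrame:
    """Tabulate per-gene metrics: length, GC partitions, ENc and (optionally) CAI."""
    rows = []
    for t in tables:
        part = gc_partition(t)
        e = enc(t)
        row = {
            "gene_id": t.label,
            "n_codons": t.total,
            "gc": part.gc,
            "gc3s": part.gc3s,
            "p1": part.p1,
            "p2": part.p2,
            "p3": part.p3,
            "p12": part.p12,
            "enc": e.enc,
        }
        if cai_model is not None:
            row["cai"] = cai(t, cai_model)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def rscu_table(counts: CodonCountTable, optimal: set[str] | None = None) -> pd.DataFrame:
    """Amino-acid / codon / RSCU table with preferred and optimal flags."""
    values = rscu(counts, include_stops=True)
    df = pd.DataFrame(
        {
            "aa": [CODON_TO_AA[c] for c in values.index],
            "rscu": values.to_numpy(),
        },
        index=values.index,
    )
    df["preferred"] = df["rscu"] > 1.0
    df["optimal"] = [c in (optimal or set()) for c in df.index]
    return df.sort_values(["aa", "rscu"], ascending=[True, False], kind="stable")
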