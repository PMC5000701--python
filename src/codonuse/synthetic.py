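"""Synthetic CDS sets with controlled mutational GC bias and translational selection.

The generator emulates an AT-rich bacterial genome: per-gene amino acids
are drawn i.i.d. from a fixed frequency vector; each amino acid is encoded
either by its designated optimal codon (with probability equal to the
gene's selection strength ``s``) or by a codon drawn from the synonymous
family with third-position G/C probability ``theta`` (the mutational GC3
bias), uniform within the G/C-ending and A/T-ending subsets.  A minority
"highly expressed" class gets a high ``s``; the background a low one.
First and second codon positions are therefore fixed by the amino-acid
draw, isolating GC3s control — the regime the neutrality plot contrasts
against P12.

All randomness flows from one master seed through named substreams
(strain index, gene index), so any single gene is reproducible in
isolation and emitted FASTA is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, CODONS, FAMILIES, SINGLE_CODON_AAS, STOP_CODONS
from .sequence_io import CodingSequence

_VARIABLE_AAS = tuple(sorted(aa for aa in FAMILIES if aa != "*" and aa not in SINGLE_CODON_AAS))

#: ribosomal-protein symbols used to annotate part of the highly expressed class
_RIBO_SYMBOLS = tuple(f"rpl{c}" for c in "ABCDEFIJKLNOPQRSUVX") + tuple(
    f"rps{c}" for c in "ABCDEGHIKLMNOPQRST"
)


def default_optimal_codons() -> dict[str, str]:
    """One designated optimal codon per variable family: T-ending preferred,
    then A-ending — mirroring the A/U-ending preference of AT-rich genomes."""
    chosen = {}
    for aa in _VARIABLE_AAS:
        fam = FAMILIES[aa]
        for end in "TA":
            cands = [c for c in fam if c[2] == end]
            if cands:
                chosen[aa] = cands[0]
                break
        else:
            chosen[aa] = fam[0]
    return chosen


def default_aa_freqs() -> dict[str, float]:
    """Uniform over the 18 variable amino acids, Met and Trp at 1% each."""
    freqs = {aa: 0.98 / len(_VARIABLE_AAS) for aa in _VARIABLE_AAS}
    freqs["M"] = 0.01
    freqs["W"] = 0.01
    return freqs


@dataclass
class SimulationConfig:
    """Study conditions for one simulated strain.

    Defaults target the AT-rich regime: GC3 mutational bias theta = 0.266,
    500 genes of 100-300 codons, a 5% highly expressed class under strong
    selection (s = 0.9) over a weakly selected background (s = 0.1).
    """

    n_genes: int = 500
    min_codons: int = 100
    max_codons: int = 300
    theta: float = 0.266
    highly_expressed_fraction: float = 0.05
    s_high: float = 0.9
    s_background: float = 0.1
    optimal_codons: Mapping[str, str] = field(default_factory=default_optimal_codons)
    aa_freqs: Mapping[str, float] = field(default_factory=default_aa_freqs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        for s in (self.s_high, self.s_background):
            if not 0 <= s <= 1:
                raise ValueError("selection strengths must lie in [0, 1]")
        if not 0 < self.highly_expressed_fraction < 1:
            raise ValueError("highly_expressed_fraction must lie in (0, 1)")
        if self.min_codons < 1 or self.max_codons < self.min_codons:
            raise ValueError("invalid gene length range")


def _family_codon_probs(aa: str, theta: float) -> dict[str, float]:
    """Mutational codon distribution within a family: third-position G/C mass
    theta, A/T mass 1-theta, uniform within each subset."""
    fam = FAMILIES[aa]
    gc = [c for c in fam if c[2] in "GC"]
    at = [c for c in fam if c[2] in "AT"]
    probs: dict[str, float] = {}
    if gc and at:
        for c in gc:
            probs[c] = theta / len(gc)
        for c in at:
            probs[c] = (1 - theta) / len(at)
    else:
        for c in fam:
            probs[c] = 1 / len(fam)
    return probs


def _codon_mixture(config: SimulationConfig, s: float, theta: float) -> np.ndarray:
    """64-dim codon sampling distribution for one expression class.

    Because amino acids are i.i.d. and the codon choice depends only on the
    amino acid, the emitted codon stream is i.i.d. from this mixture.
    """
    p = np.zeros(64)
    for aa, freq in config.aa_freqs.items():
        if aa in SINGLE_CODON_AAS:
            p[CODONS.index(FAMILIES[aa][0])] += freq
            continue
        opt = config.optimal_codons[aa]
        base = _family_codon_probs(aa, theta)
        for codon, q in base.items():
            p[CODONS.index(codon)] += freq * ((1 - s) * q + (s if codon == opt else 0.0))
    return p / p.sum()


def _gene_rng(seed: int, strain_index: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(strain_index, gene_index))
    )


def simulate_gene(
    length: int,
    expression_class: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str = "gene",
    genome_id: str = "sim",
    theta: float | None = None,
) -> CodingSequence:
    """Emit one CDS of ``length`` body codons: ATG + body + a random stop."""
    s = config.s_high if expression_class == "high" else config.s_background
    mix = _codon_mixture(config, s, config.theta if theta is None else theta)
    idx = rng.choice(64, size=length, p=mix)
    body = "".join(CODONS[i] for i in idx)
    stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
    return CodingSequence(gene_id, genome_id, "ATG" + body + stop)


@dataclass
class SyntheticGenome:
    """One simulated strain: sequences plus per-gene ground truth."""

    genome_id: str
    sequences: list[CodingSequence]
    truth: pd.DataFrame  # gene_id, expression_class, n_codons, theta, s
    config: SimulationConfig


def simulate_genome(
    config: SimulationConfig,
    genome_id: str = "sim",
    strain_index: int = 0,
    theta: float | None = None,
    s_high: float | None = None,
    s_background: float | None = None,
) -> SyntheticGenome:
    """Simulate one strain under ``config`` (with optional per-strain overrides).

    The first ``ceil(fraction * n)`` genes form the highly expressed class;
    part of that class carries ribosomal-protein annotations (symbols and
    products), the rest shared ``hegNN`` symbols, so reference selection and
    cross-strain symbol intersection work end to end.  Background genes are
    unannotated ("hypothetical protein").
    """
    cfg = config
    if s_high is not None or s_background is not None:
        cfg = replace(
            config,
            s_high=config.s_high if s_high is None else s_high,
            s_background=config.s_background if s_background is None else s_background,
        )
    th = cfg.theta if theta is None else theta
    n_high = int(np.ceil(cfg.highly_expressed_fraction * cfg.n_genes))
    n_ribo = min(n_high, (n_high + 1) // 2 + 1)
    seqs: list[CodingSequence] = []
    rows = []
    mix_cache: dict[float, np.ndarray] = {}
    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, strain_index, i)
        length = int(rng.integers(cfg.min_codons, cfg.max_codons + 1))
        cls = "high" if i < n_high else "background"
        s = cfg.s_high if cls == "high" else cfg.s_background
        key = (s, th)
        if key not in mix_cache:
            mix_cache[key] = _codon_mixture(cfg, s, th)
        idx = rng.choice(64, size=length, p=mix_cache[key])
        body = "".join(CODONS[j] for j in idx)
        stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
        gid = f"{genome_id}_g{i:04d}"
        gene = product = None
        if cls == "high":
            if i < n_ribo:
                gene = _RIBO_SYMBOLS[i % len(_RIBO_SYMBOLS)]
                product = "50S/30S ribosomal protein"
            else:
                gene = f"heg{i:02d}"
                product = "hypothetical protein"
        else:
            product = "hypothetical protein"
        seqs.append(CodingSequence(gid, genome_id, "ATG" + body + stop, gene=gene, product=product))
        rows.append(
            {
                "gene_id": gid,
                "expression_class": cls,
                "n_codons": length + 2,
                "theta": th,
                "s": s,
                "gene": gene,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return SyntheticGenome(genome_id, seqs, truth, cfg)


def simulate_strain_set(
    n_strains: int,
    divergence: float = 0.0,
    config: SimulationConfig | None = None,
    group_sizes: tuple[int, int] | None = None,
    regime_theta_shift: float = 0.01,
) -> list[SyntheticGenome]:
    """Simulate a cohort of strains around a common parameter regime.

    Each strain jitters theta and the selection strengths by N(0, divergence)
    (clipped to valid ranges) under a strain-specific substream.  When
    ``group_sizes = (a, b)`` with a+b = n_strains, two regimes are planted:
    the first group at theta - shift, the second at theta + shift, giving the
    cohort a recoverable 2-cluster structure in genome RSCU space.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    cfg = config or SimulationConfig()
    if group_sizes is not None and sum(group_sizes) != n_strains:
        raise ValueError("group sizes must sum to n_strains")
    genomes = []
    for i in range(n_strains):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10**6 + i,)))
        shift = 0.0
        if group_sizes is not None:
            shift = -regime_theta_shift if i < group_sizes[0] else regime_theta_shift
        theta = float(np.clip(cfg.theta + shift + rng.normal(0, divergence), 0.01, 0.99))
        s_high = float(np.clip(cfg.s_high + rng.normal(0, divergence), 0.0, 0.999))
        s_back = float(np.clip(cfg.s_background + rng.normal(0, divergence), 0.0, 0.999))
        genomes.append(
            simulate_genome(
                cfg,
                genome_id=f"strain{i:02d}",
                strain_index=i,
                theta=theta,
                s_high=s_high,
                s_background=s_back,
            )
        )
    return genomes


def write_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    """Write a strain as multi-FASTA with NCBI-style annotated headers."""
    with open(path, "w") as fh:
        for s in genome.sequences:
            attrs = ""
            if s.gene:
                attrs += f" [gene={s.gene}]"
            if s.product:
                attrs += f" [protein={s.product}]"
            fh.write(f">{s.gene_id}{attrs}\n")
            for i in range(0, len(s.seq), 70):
                fh.write(s.seq[i : i + 70] + "\n")


def write_truth_tsv(genome: SyntheticGenome, path: str | Path) -> None:
    genome.truth.to_csv(path, sep="\t")
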