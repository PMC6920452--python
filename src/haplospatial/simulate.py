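"""Synthetic haplotype x location matrices and COI-like sequence datasets.

Emulates the structure of an invasive-insect mtDNA COI survey: a 548-bp
protein-coding amplicon, a few dominant haplotypes plus many rare ones, and
multinomial sampling of haplotypes across locations.  Under the independence
null (``segregation_strength = 0``) every location draws haplotypes from the
same global frequency spectrum; with positive strength each location's
spectrum is a Dirichlet perturbation of the global one, mimicking spatially
segregated incursions.  Haplotypes differ from a common ancestral sequence by
transition substitutions at third codon positions, which are synonymous
under the invertebrate mitochondrial code, and optional decoy NUMT-like
sequences carrying a premature stop codon can be injected to exercise
pseudogene QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import ContingencyMatrix

__all__ = [
    "SimulationConfig",
    "dominant_plus_rare_spectrum",
    "simulate_matrix",
    "simulate_full_matrix",
    "simulate_coi_dataset",
    "CoiDataset",
]

_PURINE = {"A": "G", "G": "A"}
_PYRIMIDINE = {"C": "T", "T": "C"}
_TRANSITION = {**_PURINE, **_PYRIMIDINE}

# stop codons of the invertebrate mitochondrial code (TGA is Trp there)
_MITO_STOPS = ("TAA", "TAG")


def dominant_plus_rare_spectrum(n_haplotypes: int, n_dominant: int = 5,
                                dominant_mass: float = 0.8) -> np.ndarray:
    """Frequency spectrum with a few dominant haplotypes and a rare tail.

    The first ``n_dominant`` haplotypes share ``dominant_mass`` of the
    probability in geometrically decaying proportions; the remainder is split
    evenly across the rare tail.  Defaults mirror a survey in which ~80% of
    individuals carry one of the five commonest haplotypes.
    """
    n_dominant = min(n_dominant, n_haplotypes)
    if n_dominant < 1:
        raise ValueError("n_dominant must be >= 1")
    w = 0.5 ** np.arange(n_dominant)
    spectrum = np.zeros(n_haplotypes)
    spectrum[:n_dominant] = dominant_mass * w / w.sum()
    if n_haplotypes > n_dominant:
        spectrum[n_dominant:] = (1.0 - dominant_mass) / (n_haplotypes - n_dominant)
    else:
        spectrum /= spectrum.sum()
    return spectrum


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated survey.

    Defaults match the scale of the South American dataset: 25 haplotypes
    observed across 11 locations, 226 individuals, and a frequency spectrum
    in which the five commonest haplotypes hold 80% of the mass.
    ``segregation_strength`` interpolates between the independence null (0)
    and strongly location-segregated spectra (per-location frequencies drawn
    from Dirichlet(global_spectrum / strength), so larger values give noisier,
    more segregated spectra).
    """

    n_haplotypes: int = 25
    n_locations: int = 11
    total_observations: int = 226
    haplotype_frequency_spectrum: np.ndarray | None = None
    location_weights: np.ndarray | None = None
    segregation_strength: float = 0.0
    seed: int = 0

    spectrum: np.ndarray = field(init=False, repr=False)
    col_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.n_locations < 1:
            raise ValueError("n_haplotypes and n_locations must be positive")
        if self.total_observations < 1:
            raise ValueError("total_observations must be positive")
        if self.segregation_strength < 0:
            raise ValueError("segregation_strength must be non-negative")
        spec = (dominant_plus_rare_spectrum(self.n_haplotypes)
                if self.haplotype_frequency_spectrum is None
                else np.asarray(self.haplotype_frequency_spectrum, dtype=float))
        if spec.shape != (self.n_haplotypes,) or (spec < 0).any():
            raise ValueError("spectrum must be n_haplotypes non-negative probabilities")
        if abs(spec.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequency spectrum must sum to 1")
        w = (np.full(self.n_locations, 1.0 / self.n_locations)
             if self.location_weights is None
             else np.asarray(self.location_weights, dtype=float))
        if w.shape != (self.n_locations,) or (w < 0).any():
            raise ValueError("location_weights must be n_locations non-negative values")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("location weights must sum to 1")
        object.__setattr__(self, "spectrum", spec)
        object.__setattr__(self, "col_weights", w)

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(f"Hap_{i+1:02d}" for i in range(self.n_haplotypes))

    @property
    def col_labels(self) -> tuple[str, ...]:
        return tuple(f"Loc_{j+1:02d}" for j in range(self.n_locations))


def _location_spectra(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-location haplotype frequencies: global under the null, Dirichlet
    perturbations under segregation."""
    if config.segregation_strength == 0:
        return np.tile(config.spectrum, (config.n_locations, 1))
    alpha = np.maximum(config.spectrum / config.segregation_strength, 1e-9)
    return rng.dirichlet(alpha, size=config.n_locations)


def simulate_matrix(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> ContingencyMatrix:
    """Draw one haplotype x location count matrix.

    Each individual is assigned a location by the location weights and a
    haplotype from that location's spectrum; under ``segregation_strength=0``
    the cell counts are therefore multinomial with independent row and column
    probabilities.  Deterministic given ``config.seed`` (or an explicit rng).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    spectra = _location_spectra(config, rng)
    loc_counts = rng.multinomial(config.total_observations, config.col_weights)
    counts = np.zeros((config.n_haplotypes, config.n_locations), dtype=np.int64)
    for j, n_j in enumerate(loc_counts):
        counts[:, j] = rng.multinomial(n_j, spectra[j])
    return ContingencyMatrix(counts, config.row_labels, config.col_labels)


def simulate_full_matrix(config: SimulationConfig,
                         max_attempts: int = 1000) -> ContingencyMatrix:
    """Draw a matrix in which every haplotype and location is observed.

    A real survey table has no empty rows by construction — a haplotype is
    listed because it was observed — so templates for null-model validation
    are drawn conditionally on all rows and columns being non-empty.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(max_attempts):
        m = simulate_matrix(config, rng=rng)
        if (m.row_totals > 0).all() and (m.col_totals > 0).all():
            return m
    raise RuntimeError("could not draw a fully observed matrix; the "
                       "frequency spectrum is too sparse for this N")


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """Random open reading frame under the invertebrate mitochondrial code."""
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in _MITO_STOPS:
            codons.append(c)
    return "".join(codons)


def _third_positions(frame: int, seq_length: int) -> np.ndarray:
    """Indices of third codon positions of complete codons in the frame."""
    start = frame
    pos = np.arange(start + 2, seq_length, 3)
    return pos[pos < seq_length]


@dataclass
class CoiDataset:
    """A simulated amplicon survey: per-individual sequences plus truth."""

    sequences: dict[str, str]             # individual id -> sequence
    metadata: pd.DataFrame                # id, location, haplotype_truth, is_decoy
    haplotype_sequences: dict[str, str]   # haplotype label -> clean sequence
    matrix: ContingencyMatrix             # truth counts, decoys excluded

    def write(self, outdir: str | Path, prefix: str = "simulated") -> dict[str, Path]:
        """Write FASTA + TSV metadata + CSV count matrix; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        with open(fasta, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")
        meta = outdir / f"{prefix}.metadata.tsv"
        self.metadata.to_csv(meta, sep="\t", index=False)
        mat = outdir / f"{prefix}.matrix.csv"
        self.matrix.to_csv(mat)
        return {"fasta": fasta, "metadata": meta, "matrix": mat}


def simulate_coi_dataset(config: SimulationConfig, seq_length: int = 548,
                         frame: int = 0, decoy_rate: float = 0.0) -> CoiDataset:
    """Simulate a COI-like amplicon dataset with known haplotype truth.

    An ancestral open reading frame is generated (no in-frame stops under the
    invertebrate mitochondrial code, trailing partial codon allowed), and
    haplotype ``k`` (1-based) differs from it by ``k-1`` transition
    substitutions at distinct third codon positions — synonymous by
    construction, as in real COI haplotype surveys where variation is
    dominated by silent third-position transitions.  Individuals get
    haplotypes and locations from :func:`simulate_matrix`.  With
    ``decoy_rate > 0`` each individual is independently replaced, with that
    probability, by a NUMT-like pseudogene copy of its haplotype carrying a
    premature stop codon; decoys are flagged in the metadata and excluded
    from the truth matrix.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValueError("decoy_rate must be in [0, 1]")
    rng = np.random.default_rng(config.seed)

    third = _third_positions(frame, seq_length)
    if config.n_haplotypes - 1 > third.size:
        raise ValueError("not enough third codon positions for the requested "
                         "number of distinct haplotypes")

    n_codons = (seq_length - frame) // 3
    orf = _random_orf(n_codons, rng)
    prefix = "".join(rng.choice(list("ACGT"), size=frame))
    tail_len = seq_length - frame - 3 * n_codons
    tail = "".join(rng.choice(list("ACGT"), size=tail_len))
    ancestor = prefix + orf + tail
    assert len(ancestor) == seq_length

    # nested substitution sets guarantee all haplotypes are pairwise distinct
    mut_pool = rng.permutation(third)
    hap_seqs: dict[str, str] = {}
    for k, label in enumerate(config.row_labels):
        seq = list(ancestor)
        for pos in mut_pool[:k]:
            seq[pos] = _TRANSITION[seq[pos]]
        hap_seqs[label] = "".join(seq)

    matrix = simulate_matrix(config, rng=rng)

    ids, locs, haps, decoys, seqs = [], [], [], [], {}
    idx = 0
    decoy_draw = rng.random(config.total_observations)
    # stop is placed at an internal codon, never the first or last
    counts = matrix.counts.copy()
    for i, hap in enumerate(config.row_labels):
        for j, loc in enumerate(config.col_labels):
            for _ in range(int(counts[i, j])):
                name = f"ind_{idx+1:04d}"
                is_decoy = bool(decoy_draw[idx] < decoy_rate)
                seq = hap_seqs[hap]
                if is_decoy:
                    codon_idx = int(rng.integers(1, n_codons - 1))
                    pos = frame + 3 * codon_idx
                    stop = _MITO_STOPS[int(rng.integers(len(_MITO_STOPS)))]
                    seq = seq[:pos] + stop + seq[pos + 3:]
                ids.append(name)
                locs.append(loc)
                haps.append(hap)
                decoys.append(is_decoy)
                seqs[name] = seq
                idx += 1

    meta = pd.DataFrame({"id": ids, "location": locs,
                         "haplotype_truth": haps, "is_decoy": decoys})
    clean = meta[~meta.is_decoy]
    truth = np.zeros_like(matrix.counts)
    row_ix = {h: i for i, h in enumerate(config.row_labels)}
    col_ix = {c: j for j, c in enumerate(config.col_labels)}
    for h, c in zip(clean.haplotype_truth, clean.location):
        truth[row_ix[h], col_ix[c]] += 1
    truth_matrix = ContingencyMatrix(truth, config.row_labels, config.col_labels)
    return CoiDataset(sequences=seqs, metadata=meta,
                      haplotype_sequences=hap_seqs, matrix=truth_matrix)
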