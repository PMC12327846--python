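"""Synthetic ChAP-Seq data with planted ground truth.

Generates toy circular bacterial genomes, non-overlapping gene models,
planted Gaussian-shaped binding peaks with condition-specific presence,
motif instances written into the sequence, per-replicate coverage tracks
(optionally Poisson-noised), and differential-expression tables. The
planted truth is the oracle for every downstream recovery test.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# FWHM of a Gaussian = 2*sqrt(2*ln 2)*sigma ~= 2.355*sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PlacementError(ValueError):
    """Raised when genes or peaks cannot be placed under the constraints."""


@dataclass(frozen=True)
class GenomeSequence:
    chrom_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene on a bacterial chromosome.

    Coordinates are 0-based half-open; ``tss`` is the transcriptional
    start site: ``start`` for a + strand gene, ``end - 1`` for a − strand
    gene (both inside the gene body).
    """

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PlantedPeak:
    summit: int
    height: float
    width: float  # FWHM of the planted Gaussian bump, bp
    condition_mask: frozenset = frozenset()
    motif_planted: bool = False

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        if self.width < 5:
            raise ValueError("peak width must be >= 5 bp")


@dataclass
class SyntheticTruth:
    """Planted ground truth: genome, genes, peaks, background level."""

    genome: GenomeSequence
    genes: list
    peaks: list
    background_mean: float
    conditions: list
    seed: int

    def peaks_in(self, condition: str) -> list:
        return [p for p in self.peaks if condition in p.condition_mask]

    # -- JSON sidecar ------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "genome": {"chrom_id": self.genome.chrom_id,
                       "sequence": self.genome.sequence,
                       "circular": self.genome.circular},
            "genes": [asdict(g) for g in self.genes],
            "peaks": [{"summit": p.summit, "height": p.height,
                       "width": p.width,
                       "condition_mask": sorted(p.condition_mask),
                       "motif_planted": p.motif_planted}
                      for p in self.peaks],
            "background_mean": self.background_mean,
            "conditions": list(self.conditions),
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            genome=GenomeSequence(**d["genome"]),
            genes=[GeneModel(**g) for g in d["genes"]],
            peaks=[PlantedPeak(summit=p["summit"], height=p["height"],
                               width=p["width"],
                               condition_mask=frozenset(p["condition_mask"]),
                               motif_planted=p["motif_planted"])
                   for p in d["peaks"]],
            background_mean=d["background_mean"],
            conditions=d["conditions"],
            seed=d["seed"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())


def circular_distance(a: int, b: int, length: int) -> int:
    d = abs(int(a) - int(b)) % length
    return min(d, length - d)


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def generate_genome(length: int, gc_fraction: float = 0.54, n_genes: int = 40,
                    circular: bool = True, seed: int = 0,
                    chrom_id: str = "chr",
                    gene_length_range: tuple = (600, 1500),
                    min_gap: int = 100):
    """Random genome sequence plus non-overlapping gene models.

    GC content is controlled per base; genes are placed left to right with
    random gaps (Dirichlet-distributed leftover space), random strands, and
    are returned sorted by start. Deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 bp")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    genome = GenomeSequence(chrom_id, seq, circular)

    genes: list = []
    if n_genes > 0:
        lo, hi = gene_length_range
        lens = rng.integers(lo, hi + 1, size=n_genes)
        slack = length - int(lens.sum()) - min_gap * n_genes
        if slack < 0:
            raise PlacementError(
                f"cannot place {n_genes} non-overlapping genes of total "
                f"length {int(lens.sum())} (+gaps) on a {length} bp genome")
        # split the slack into n_genes+1 random gaps
        gaps = np.floor(rng.dirichlet(np.ones(n_genes + 1)) * slack).astype(int)
        strands = rng.choice(["+", "-"], size=n_genes)
        if n_genes >= 2 and len(set(strands)) == 1:
            strands[rng.integers(n_genes)] = "+" if strands[0] == "-" else "-"
        pos = 0
        width = len(str(n_genes))
        for i in range(n_genes):
            pos += int(gaps[i]) + min_gap // 2
            genes.append(GeneModel(f"gene_{i + 1:0{width}d}", pos,
                                   pos + int(lens[i]), str(strands[i])))
            pos += int(lens[i]) + (min_gap - min_gap // 2)
        genes.sort(key=lambda g: g.start)
    return genome, genes


# ---------------------------------------------------------------------------
# planted peaks
# ---------------------------------------------------------------------------

def _condition_masks(n_peaks, conditions, condition_counts, rng):
    conditions = list(conditions)
    if condition_counts is not None:
        masks = []
        for pattern, count in condition_counts.items():
            fs = frozenset([pattern] if isinstance(pattern, str) else pattern)
            if not fs <= set(conditions):
                raise ValueError(f"unknown condition(s) in pattern {pattern}")
            masks.extend([fs] * count)
        if len(masks) != n_peaks:
            raise ValueError(
                f"condition_counts sum to {len(masks)}, expected {n_peaks}")
        rng.shuffle(masks)
        return masks
    if len(conditions) == 1:
        return [frozenset(conditions)] * n_peaks
    # uniform over non-empty subsets of the condition labels
    subsets = []
    for bits in range(1, 2 ** len(conditions)):
        subsets.append(frozenset(c for j, c in enumerate(conditions)
                                 if bits >> j & 1))
    idx = rng.integers(len(subsets), size=n_peaks)
    return [subsets[i] for i in idx]


def plant_peaks(genome: GenomeSequence, genes: Sequence, n_peaks: int,
                height_range: tuple = (30.0, 300.0),
                width_range: tuple = (40.0, 120.0),
                upstream_fraction: float = 0.8,
                conditions: Sequence = ("iron",),
                background_mean: float = 10.0,
                seed: int = 0,
                condition_counts: Mapping | None = None,
                upstream_window: int = 500,
                motif_fraction: float = 0.0,
                max_tries: int = 10000) -> SyntheticTruth:
    """Plant well-separated Gaussian binding peaks on the genome.

    ``upstream_fraction`` of summits go into the oriented upstream window of
    some gene TSS (outside any gene body); the rest go inside gene bodies.
    Distinct summits are kept >= 2x the larger of the two widths apart.
    ``condition_counts`` optionally fixes the number of peaks per
    condition-presence pattern, e.g. ``{("iron",): 11, ("heme",): 17,
    ("iron","heme"): 3}``.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    if height_range[0] <= 0 or width_range[0] <= 0:
        raise ValueError("height/width ranges must be positive")
    rng = np.random.default_rng(seed)
    L = len(genome)
    masks = _condition_masks(n_peaks, conditions, condition_counts, rng)

    n_up = int(round(upstream_fraction * n_peaks))
    want_upstream = [True] * n_up + [False] * (n_peaks - n_up)
    rng.shuffle(want_upstream)

    # candidate position pools
    gene_bodies = [(g.start, g.end) for g in genes]

    def in_gene(pos):
        return any(s <= pos < e for s, e in gene_bodies)

    def upstream_pos():
        g = genes[rng.integers(len(genes))]
        off = int(rng.integers(20, upstream_window))
        pos = (g.tss - off) % L if g.strand == "+" else (g.tss + off) % L
        return pos if (genome.circular or 0 <= pos < L) else None

    def orf_pos():
        g = genes[rng.integers(len(genes))]
        margin = max(5, (g.end - g.start) // 10)
        if g.end - margin <= g.start + margin:
            return None
        return int(rng.integers(g.start + margin, g.end - margin))

    peaks: list = []
    n_motif = int(round(motif_fraction * n_peaks))
    for k in range(n_peaks):
        width = float(rng.uniform(*width_range))
        height = float(rng.uniform(*height_range))
        placed = False
        for _ in range(max_tries):
            if want_upstream[k]:
                if not genes:
                    raise PlacementError("upstream placement needs genes")
                pos = upstream_pos()
                if pos is None or in_gene(pos):
                    continue
            else:
                if not genes:
                    pos = int(rng.integers(L))
                else:
                    pos = orf_pos()
                    if pos is None:
                        continue
            sep_ok = all(
                circular_distance(pos, q.summit, L)
                >= 2 * max(width, q.width)
                for q in peaks)
            if sep_ok:
                peaks.append(PlantedPeak(pos, height, width, masks[k],
                                         motif_planted=k < n_motif))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place peak {k + 1}/{n_peaks} under the "
                f">=2x-width separation constraint")

    truth = SyntheticTruth(genome, list(genes), peaks, background_mean,
                           list(conditions), seed)
    _check_separation(truth)
    return truth


def _check_separation(truth: SyntheticTruth) -> None:
    L = len(truth.genome)
    for i, a in enumerate(truth.peaks):
        for b in truth.peaks[i + 1:]:
            need = 2 * max(a.width, b.width)
            if circular_distance(a.summit, b.summit, L) < need:
                raise PlacementError("planted peaks violate separation")


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def expected_profile(truth: SyntheticTruth, condition: str) -> np.ndarray:
    """Noise-free expected depth: background + sum of Gaussian bumps."""
    L = len(truth.genome)
    x = np.arange(L)
    mu = np.full(L, float(truth.background_mean))
    for p in truth.peaks_in(condition):
        d = np.abs(x - p.summit)
        if truth.genome.circular:
            d = np.minimum(d, L - d)
        sigma = p.width / FWHM_TO_SIGMA
        mu += p.height * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return mu


def simulate_coverage(truth: SyntheticTruth, condition: str,
                      replicate: int = 1, noise: str = "poisson",
                      seed: int = 0, height_scale: float = 1.0):
    """One replicate coverage track for one condition.

    ``noise="none"`` returns the expectation rounded to the nearest
    integer; ``"poisson"`` draws per-base Poisson counts with that mean.
    The replicate index and condition both enter the random stream, so
    replicates of a condition differ while remaining seed-reproducible.
    """
    from .coverage import CoverageTrack  # local import to avoid cycle

    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    mu = expected_profile(truth, condition)
    if height_scale != 1.0:
        mu = truth.background_mean + (mu - truth.background_mean) * height_scale
    if noise == "none":
        values = np.rint(mu).astype(np.int64)
    elif noise == "poisson":
        cond_idx = truth.conditions.index(condition)
        rng = np.random.default_rng([seed, cond_idx, replicate])
        values = rng.poisson(mu)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return CoverageTrack(chrom=truth.genome.chrom_id,
                         values=values.astype(np.float64),
                         sample=f"{condition}_rep{replicate}",
                         condition=condition, replicate=replicate,
                         circular=truth.genome.circular)


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def plant_motif(genome: GenomeSequence, truth: SyntheticTruth,
                consensus: str, seed: int = 0) -> GenomeSequence:
    """Overwrite the sequence around each motif-flagged summit with one
    concrete realization of the IUPAC consensus (ambiguity codes resolved
    randomly per site, seeded). Other positions are untouched."""
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s): {sorted(bad)}")
    for p in truth.peaks:
        if p.motif_planted and len(consensus) >= p.width:
            raise ValueError("consensus must be shorter than planted widths")
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    L = len(seq)
    m = len(consensus)
    for p in truth.peaks:
        if not p.motif_planted:
            continue
        start = p.summit - m // 2
        if not genome.circular and (start < 0 or start + m > L):
            raise ValueError("consensus overlaps the end of a linear genome")
        word = "".join(IUPAC[c][rng.integers(len(IUPAC[c]))]
                       for c in consensus)
        for j, base in enumerate(word):
            seq[(start + j) % L] = base
    return GenomeSequence(genome.chrom_id, "".join(seq), genome.circular)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def nearest_gene(summit: int, genes: Sequence, length: int):
    """Gene with the TSS closest (circular distance) to the summit."""
    return min(genes, key=lambda g: (circular_distance(summit, g.tss, length),
                                     g.gene_id))


def simulate_expression(truth: SyntheticTruth, model: str = "null",
                        noise_sd: float = 1.0, seed: int = 0,
                        slope: float = 1.0):
    """Differential-expression table (gene_id, log2_ratio).

    ``null``: every gene gets an independent N(0, noise_sd) log2 ratio.
    ``anti_proportional``: the gene nearest each planted peak gets a
    negative log2 ratio whose magnitude decreases with the peak's height
    rank (strongest binding -> weakest expression change), emulating an
    anti-proportional binding/expression trend; remaining genes get null
    draws.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    L = len(truth.genome)
    ratios = {g.gene_id: (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
              for g in truth.genes}
    if model == "null":
        pass
    elif model == "anti_proportional":
        # strongest peak wins when several share a nearest gene
        peaks = sorted(truth.peaks, key=lambda p: p.height)
        n = len(peaks)
        for rank, p in enumerate(peaks):  # rank 0 = smallest height
            g = nearest_gene(p.summit, truth.genes, L)
            magnitude = slope * (n - rank)  # decreases as height grows
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            ratios[g.gene_id] = -(magnitude + noise)  # later = taller
    else:
        raise ValueError(f"unknown expression model {model!r}")
    return pd.DataFrame({"gene_id": list(ratios), "log2_ratio":
                         [ratios[g] for g in ratios]})


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------

def write_fasta(genome: GenomeSequence, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rec = SeqRecord(Seq(genome.sequence), id=genome.chrom_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path, circular: bool = True) -> GenomeSequence:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return GenomeSequence(rec.id, str(rec.seq).upper(), circular)


def write_gff3(genes: Sequence, chrom_id: str, path) -> None:
    """GFF3 ``gene`` features, 1-based inclusive coordinates, ID= attrs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{chrom_id}\tchapkit\tgene\t{g.start + 1}\t{g.end}\t"
                     f".\t{g.strand}\t.\tID={g.gene_id}\n")
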