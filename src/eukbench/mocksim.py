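"""Mock-metagenome simulation.

Stands in for genome retrieval, read simulation/assembly, and the
external classifiers themselves. Three generators cover the benchmark's
inputs:

* :func:`sample_composition` draws per-sample genome abundances from a
  lognormal distribution (``mu=1``, ``sigma=2`` on the log scale, the
  convention of read simulators) and rescales the eukaryotic abundances
  so that the eukaryote:prokaryote base-pair ratio is *exactly* the
  target (0.05 by default) in every sample, not merely in expectation.
* :func:`extract_test_contigs` cuts fixed-length test fragments
  (1/3/5 kbp, 100 per genome per length by default) out of a genome
  catalog's contigs, recording each fragment's true superkingdom.
* :func:`simulate_calls` emulates classifier outputs from
  length-stratified error profiles (sensitivity, specificity and an
  ``unclassified`` outcome per length bin), so ensemble and benchmark
  code can be exercised without any external tool.

A fourth helper, :func:`simulate_bins`, perturbs a gold-standard
contig→genome map into a plausible binning result for exercising the
bin-quality metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import validate_call_table, validate_contig_manifest

__all__ = [
    "Genome",
    "GenomeCatalog",
    "CompositionConfig",
    "LengthBin",
    "ErrorProfile",
    "random_catalog",
    "sample_composition",
    "extract_test_contigs",
    "simulate_calls",
    "simulate_bins",
    "default_profiles",
]


@dataclass(frozen=True)
class Genome:
    """One catalog genome: id, superkingdom, and its contig lengths (bp)."""

    genome_id: str
    superkingdom: str  # "eukaryote" | "prokaryote"
    contig_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.superkingdom not in ("eukaryote", "prokaryote"):
            raise ValueError(f"superkingdom must be eukaryote/prokaryote, got {self.superkingdom!r}")
        if not self.contig_lengths or any(l < 1 for l in self.contig_lengths):
            raise ValueError(f"{self.genome_id}: contig lengths must be positive")

    @property
    def total_length_bp(self) -> int:
        return int(sum(self.contig_lengths))


@dataclass(frozen=True)
class GenomeCatalog:
    genomes: tuple[Genome, ...]

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("catalog must not be empty")
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in catalog")

    def subset(self, superkingdom: str) -> tuple[Genome, ...]:
        return tuple(g for g in self.genomes if g.superkingdom == superkingdom)

    def require_both_superkingdoms(self) -> None:
        for sk in ("eukaryote", "prokaryote"):
            if not self.subset(sk):
                raise ValueError(f"catalog has no {sk} genome")


@dataclass(frozen=True)
class CompositionConfig:
    """Lognormal abundance model with an imposed eukaryote bp ratio.

    ``mu``/``sigma`` parameterize the underlying normal of the
    lognormal on the log scale. ``euk_prok_bp_ratio`` is the exact
    eukaryote:prokaryote total-bp ratio imposed on every sample.
    """

    mu: float = 1.0
    sigma: float = 2.0
    euk_prok_bp_ratio: float = 0.05
    n_samples: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.euk_prok_bp_ratio <= 0:
            raise ValueError("euk_prok_bp_ratio must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def random_catalog(
    n_euk: int = 33,
    n_prok: int = 216,
    seed: int = 0,
    euk_genome_size_bp: tuple[int, int] = (10_000_000, 50_000_000),
    prok_genome_size_bp: tuple[int, int] = (2_000_000, 8_000_000),
    mean_contig_bp: int = 100_000,
) -> GenomeCatalog:
    """Random genome catalog with realistic size contrasts.

    Defaults mirror a benchmark catalog of 33 eukaryotic and 216
    prokaryotic genomes; eukaryotic genomes are drawn an order of
    magnitude larger than prokaryotic ones. Each genome is split into
    contigs with exponentially distributed lengths (min 5 kbp) around
    ``mean_contig_bp``.
    """
    rng = np.random.default_rng(seed)
    genomes: list[Genome] = []

    def split(total: int) -> tuple[int, ...]:
        lengths: list[int] = []
        remaining = total
        while remaining > 0:
            l = int(min(remaining, max(5000, rng.exponential(mean_contig_bp))))
            lengths.append(l)
            remaining -= l
        return tuple(lengths)

    for i in range(n_euk):
        size = int(rng.uniform(*euk_genome_size_bp))
        genomes.append(Genome(f"euk_{i:03d}", "eukaryote", split(size)))
    for i in range(n_prok):
        size = int(rng.uniform(*prok_genome_size_bp))
        genomes.append(Genome(f"prok_{i:03d}", "prokaryote", split(size)))
    return GenomeCatalog(tuple(genomes))


def sample_composition(
    catalog: GenomeCatalog, cfg: CompositionConfig = CompositionConfig()
) -> pd.DataFrame:
    """Draw mock-metagenome compositions with an exact eukaryote bp ratio.

    For each sample, per-genome abundances ``a_g ~ LogNormal(mu, sigma)``
    give bp shares ``b_g = a_g * total_length_bp(g)``. All eukaryotic
    abundances are then rescaled by one constant so that
    ``sum(b_euk) / sum(b_prok)`` equals ``euk_prok_bp_ratio`` exactly,
    leaving the relative structure within each superkingdom intact, and
    abundances are renormalized to sum to 1.

    Returns a long DataFrame: sample_id, genome_id, superkingdom,
    abundance (sums to 1 per sample), bp_share (fraction of sample bp,
    sums to 1 per sample).
    """
    catalog.require_both_superkingdoms()
    rng = np.random.default_rng(cfg.seed)
    sk = np.array([g.superkingdom for g in catalog.genomes])
    sizes = np.array([g.total_length_bp for g in catalog.genomes], dtype=float)
    is_euk = sk == "eukaryote"

    frames = []
    for s in range(cfg.n_samples):
        a = rng.lognormal(mean=cfg.mu, sigma=cfg.sigma, size=len(catalog.genomes))
        b = a * sizes
        c = cfg.euk_prok_bp_ratio * b[~is_euk].sum() / b[is_euk].sum()
        a = np.where(is_euk, a * c, a)
        b = a * sizes
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"sample_{s:02d}",
                    "genome_id": [g.genome_id for g in catalog.genomes],
                    "superkingdom": sk,
                    "abundance": a / a.sum(),
                    "bp_share": b / b.sum(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def extract_test_contigs(
    catalog: GenomeCatalog,
    lengths: Sequence[int] = (1000, 3000, 5000),
    n_per_genome: int = 100,
    seed: int = 0,
    sequences: Mapping[str, Sequence[str]] | None = None,
    fasta_out: str | Path | None = None,
) -> pd.DataFrame:
    """Extract fixed-length test fragments from catalog contigs.

    For each genome and each target length, ``n_per_genome`` fragments
    are drawn with uniformly random start positions from the genome's
    contigs of at least that length (source contigs chosen uniformly
    among the eligible ones; overlapping fragments are allowed). A
    genome with no contig long enough for a target length is skipped for
    that length with a warning.

    When ``sequences`` maps genome ids to per-contig sequence strings
    (matching ``contig_lengths``), the fragments' sequences are written
    to ``fasta_out`` as FASTA.

    Returns a contig manifest whose ``true_label`` is the source
    genome's superkingdom.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    records: list[tuple[str, str]] = []
    for genome in catalog.genomes:
        contig_lengths = np.asarray(genome.contig_lengths)
        for target in lengths:
            eligible = np.flatnonzero(contig_lengths >= target)
            if eligible.size == 0:
                warnings.warn(
                    f"{genome.genome_id}: no contig >= {target} bp; "
                    f"skipped for this length",
                    stacklevel=2,
                )
                continue
            src = rng.choice(eligible, size=n_per_genome, replace=True)
            starts = rng.integers(0, contig_lengths[src] - target + 1)
            for k, (ci, st) in enumerate(zip(src, starts)):
                frag_id = f"{genome.genome_id}.c{ci}.{target}bp.{k:03d}"
                rows.append(
                    {
                        "contig_id": frag_id,
                        "length_bp": int(target),
                        "true_label": genome.superkingdom,
                        "source_genome_id": genome.genome_id,
                    }
                )
                if sequences is not None:
                    seq = sequences[genome.genome_id][ci]
                    records.append((frag_id, seq[st : st + target]))
    manifest = validate_contig_manifest(pd.DataFrame(rows))
    if sequences is not None and fasta_out is not None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        seqio_write(
            (SeqRecord(Seq(s), id=i, description="") for i, s in records),
            str(fasta_out),
            "fasta",
        )
    return manifest


@dataclass(frozen=True)
class LengthBin:
    """Classifier behaviour on contigs with ``min_bp <= length < max_bp``.

    ``sensitivity`` is the probability a true eukaryotic contig is
    called eukaryote; ``specificity`` the probability a true
    non-eukaryotic contig is called noneukaryote; the tool returns
    ``unclassified`` with probability ``unclassified_rate`` on either
    class, and the wrong label with the remaining probability.
    """

    min_bp: int
    max_bp: int | None  # None = unbounded
    sensitivity: float
    specificity: float
    unclassified_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "unclassified_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sensitivity + self.unclassified_rate > 1 + 1e-12:
            raise ValueError("sensitivity + unclassified_rate must be <= 1")
        if self.specificity + self.unclassified_rate > 1 + 1e-12:
            raise ValueError("specificity + unclassified_rate must be <= 1")
        if self.max_bp is not None and self.max_bp <= self.min_bp:
            raise ValueError("max_bp must exceed min_bp")

    def contains(self, length_bp: np.ndarray) -> np.ndarray:
        upper = np.inf if self.max_bp is None else self.max_bp
        return (length_bp >= self.min_bp) & (length_bp < upper)


@dataclass(frozen=True)
class ErrorProfile:
    """Length-stratified error model for one emulated classifier."""

    tool_id: str
    bins: tuple[LengthBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("profile needs at least one length bin")


def flat_profile(
    tool_id: str,
    sensitivity: float,
    specificity: float,
    unclassified_rate: float = 0.0,
) -> ErrorProfile:
    """Single-bin profile covering all contig lengths."""
    return ErrorProfile(
        tool_id,
        (LengthBin(1, None, sensitivity, specificity, unclassified_rate),),
    )


def default_profiles() -> list[ErrorProfile]:
    """Emulated tool panel with realistic length-dependent behaviour.

    Three k-mer classifiers whose accuracy improves with contig length
    and one reference-style tool that is near-perfect when it answers
    but leaves a large share of (especially eukaryotic) contigs without
    annotation.
    """
    def kmer(tool_id: str, s1: float, s3: float, s5: float, p1: float, p3: float, p5: float) -> ErrorProfile:
        return ErrorProfile(
            tool_id,
            (
                LengthBin(1, 3000, s1, p1),
                LengthBin(3000, 5000, s3, p3),
                LengthBin(5000, None, s5, p5),
            ),
        )

    ref = ErrorProfile(
        "kaiju",
        (
            LengthBin(1, 3000, 0.47, 0.49, unclassified_rate=0.50),
            LengthBin(3000, None, 0.57, 0.59, unclassified_rate=0.40),
        ),
    )
    return [
        kmer("tiara", 0.80, 0.92, 0.95, 0.95, 0.97, 0.98),
        kmer("whokaryote", 0.75, 0.88, 0.92, 0.93, 0.95, 0.97),
        kmer("deepmicrobefinder", 0.78, 0.90, 0.93, 0.90, 0.94, 0.96),
        ref,
    ]


def simulate_calls(
    manifest: pd.DataFrame,
    profiles: Iterable[ErrorProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate per-tool classifier calls from error profiles.

    Each contig's length must fall into exactly one bin of every
    profile; contigs with ``true_label`` ``virus`` are treated as
    non-eukaryotic, ``unknown`` labels are rejected.
    """
    if (manifest["true_label"] == "unknown").any():
        raise ValueError("simulate_calls needs known true labels")
    rng = np.random.default_rng(seed)
    length = manifest["length_bp"].to_numpy()
    is_euk = (manifest["true_label"] == "eukaryote").to_numpy()
    frames = []
    for profile in profiles:
        coverage = np.zeros(len(manifest), dtype=int)
        sens = np.empty(len(manifest))
        spec = np.empty(len(manifest))
        uncl = np.empty(len(manifest))
        for b in profile.bins:
            mask = b.contains(length)
            coverage += mask
            sens[mask] = b.sensitivity
            spec[mask] = b.specificity
            uncl[mask] = b.unclassified_rate
        if (coverage != 1).any():
            bad = length[coverage != 1][0]
            raise ValueError(
                f"{profile.tool_id}: length {bad} bp falls in {0 if (coverage == 0).any() else 2}+ bins; "
                "bins must tile contig lengths exactly once"
            )
        u = rng.random(len(manifest))
        correct = np.where(is_euk, sens, spec)
        label_correct = np.where(is_euk, "eukaryote", "noneukaryote")
        label_wrong = np.where(is_euk, "noneukaryote", "eukaryote")
        call = np.where(
            u < correct,
            label_correct,
            np.where(u < correct + uncl, "unclassified", label_wrong),
        )
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": manifest["contig_id"].to_numpy(),
                    "tool_id": profile.tool_id,
                    "raw_label": call,
                    "norm_label": call,
                }
            )
        )
    return validate_call_table(pd.concat(frames, ignore_index=True))


def simulate_bins(
    goldmap: pd.DataFrame,
    miss_rate: float = 0.1,
    misassign_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Perturb a gold contig→genome map into a synthetic binning result.

    Each contig is binned to its source genome's bin, except that with
    probability ``miss_rate`` it is left unbinned, and with probability
    ``misassign_rate`` it is placed into another genome's bin chosen
    uniformly at random.
    """
    rng = np.random.default_rng(seed)
    genomes = goldmap["source_genome_id"].unique()
    bins = "bin_" + goldmap["source_genome_id"].astype(str)
    u = rng.random(len(goldmap))
    out = bins.to_numpy(dtype=object)
    unbinned = u < miss_rate
    wrong = (u >= miss_rate) & (u < miss_rate + misassign_rate)
    out[unbinned] = "unbinned"
    if wrong.any():
        out[wrong] = ["bin_" + g for g in rng.choice(genomes, size=int(wrong.sum()))]
    return pd.DataFrame({"contig_id": goldmap["contig_id"].to_numpy(), "bin_id": out})
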