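"""Hybrid ensemble classification of contigs as eukaryotic or not.

The decision logic combines two families of classifiers:

* a *reference-based* tool (protein/sequence alignment against a
  database) whose call, when it made one, is trusted first;
* a panel of *k-mer-based* tools combined by majority vote with ties
  excluded: votes of ``unclassified`` are discarded, the strict majority
  of the remaining votes wins, and an exact tie (or no informative vote)
  yields ``unclassified``.

Because short contigs carry little signal, each family has its own
minimum contig length: reference calls are used from 1 kbp, k-mer votes
only from 3 kbp (both configurable). A contig below the reference
threshold is never classified; one between the two thresholds is
classified only if the reference tool annotated it.

A reference call of ``noneukaryote`` takes precedence just like a
eukaryote call: downstream binning strategies rely on contigs being
positively identified as prokaryotic/viral, not only on positive
eukaryote identifications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import NORM_LABELS, validate_call_table, validate_final_table

__all__ = [
    "EnsembleConfig",
    "majority_vote",
    "hybrid_classify",
    "classify_assembly",
]

#: Default k-mer panel: the Tiara + Whokaryote + DeepMicrobeFinder
#: combination ("majority without EukRep"), the best-performing panel in
#: benchmark testing; the reference tool defaults to Kaiju.
DEFAULT_KMER_TOOLS = ("tiara", "whokaryote", "deepmicrobefinder")
DEFAULT_REF_TOOL = "kaiju"


class EnsembleConfigError(ValueError):
    """Invalid ensemble configuration."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Tool panel and length thresholds for the hybrid classifier.

    Attributes
    ----------
    kmer_tools:
        Tool ids whose calls enter the majority vote (at least one).
    ref_tool:
        Tool id whose call takes precedence when present.
    min_len_ref_bp:
        Minimum contig length for using the reference call (default 1000).
    min_len_kmer_bp:
        Minimum contig length for using the k-mer vote (default 3000);
        must be >= ``min_len_ref_bp``.
    """

    kmer_tools: tuple[str, ...] = DEFAULT_KMER_TOOLS
    ref_tool: str = DEFAULT_REF_TOOL
    min_len_ref_bp: int = 1000
    min_len_kmer_bp: int = 3000

    def __post_init__(self) -> None:
        if not self.kmer_tools:
            raise EnsembleConfigError("kmer_tools must not be empty")
        if len(set(self.kmer_tools)) != len(self.kmer_tools):
            raise EnsembleConfigError("kmer_tools contains duplicates")
        if self.min_len_ref_bp < 1 or self.min_len_kmer_bp < 1:
            raise EnsembleConfigError("length thresholds must be positive")
        if self.min_len_ref_bp > self.min_len_kmer_bp:
            raise EnsembleConfigError(
                "min_len_ref_bp must not exceed min_len_kmer_bp"
            )


def majority_vote(votes: Iterable[str]) -> str:
    """Strict-majority label among informative votes; ties excluded.

    ``unclassified`` votes are discarded before counting. Returns the
    label held by a strict majority of the remaining votes, or
    ``unclassified`` on an exact tie or when no informative vote remains.
    """
    counts = Counter(v for v in votes if v != "unclassified")
    unknown = set(counts) - set(NORM_LABELS)
    if unknown:
        raise ValueError(f"votes outside vocabulary: {sorted(unknown)!r}")
    if not counts:
        return "unclassified"
    euk = counts.get("eukaryote", 0)
    non = counts.get("noneukaryote", 0)
    if euk > non:
        return "eukaryote"
    if non > euk:
        return "noneukaryote"
    return "unclassified"


def hybrid_classify(
    length_bp: int,
    ref_call: str,
    kmer_votes: Sequence[str],
    cfg: EnsembleConfig = EnsembleConfig(),
) -> tuple[str, str]:
    """Classify one contig; returns ``(final_label, decided_by)``.

    ``decided_by`` is ``reference`` when the reference call was used,
    ``kmer_vote`` when the majority vote produced a label, and ``none``
    when the contig stays unclassified.
    """
    if length_bp >= cfg.min_len_ref_bp and ref_call != "unclassified":
        if ref_call not in NORM_LABELS:
            raise ValueError(f"reference call outside vocabulary: {ref_call!r}")
        return ref_call, "reference"
    if length_bp >= cfg.min_len_kmer_bp:
        label = majority_vote(kmer_votes)
        if label != "unclassified":
            return label, "kmer_vote"
    return "unclassified", "none"


def _votes_matrix(
    manifest: pd.DataFrame, calls: pd.DataFrame, tools: Sequence[str]
) -> pd.DataFrame:
    """Wide per-tool label matrix aligned to the manifest; missing -> unclassified."""
    if calls.empty:
        return pd.DataFrame(
            "unclassified", index=manifest["contig_id"], columns=list(tools)
        )
    wide = calls.pivot(index="contig_id", columns="tool_id", values="norm_label")
    wide = wide.reindex(index=manifest["contig_id"], columns=list(tools))
    return wide.fillna("unclassified")


def classify_assembly(
    manifest: pd.DataFrame,
    calls: pd.DataFrame,
    cfg: EnsembleConfig = EnsembleConfig(),
) -> pd.DataFrame:
    """Apply the hybrid rule to every contig of an assembly.

    Parameters
    ----------
    manifest:
        Contig manifest (``contig_id``, ``length_bp``, ...).
    calls:
        Normalized call table; may cover any subset of the manifest's
        contigs and tools. A missing (contig, tool) pair counts as an
        ``unclassified`` vote. Calls for the configured ``ref_tool``
        provide the reference annotation.

    Returns
    -------
    DataFrame with one row per manifest contig: ``contig_id``,
    ``final_label``, ``decided_by``. Deterministic given its inputs.
    """
    calls = validate_call_table(calls) if len(calls) else calls
    if len(calls):
        unknown = set(calls["contig_id"]) - set(manifest["contig_id"])
        if unknown:
            raise ValueError(
                f"calls reference contigs absent from the manifest: "
                f"{sorted(unknown)[:5]!r}"
            )
    tools = [cfg.ref_tool, *cfg.kmer_tools]
    wide = _votes_matrix(manifest, calls, tools)
    length = manifest["length_bp"].to_numpy()

    labels = wide[list(cfg.kmer_tools)].to_numpy()
    euk_votes = (labels == "eukaryote").sum(axis=1)
    non_votes = (labels == "noneukaryote").sum(axis=1)
    vote = np.where(
        euk_votes > non_votes,
        "eukaryote",
        np.where(non_votes > euk_votes, "noneukaryote", "unclassified"),
    )
    ref = wide[cfg.ref_tool].to_numpy()

    use_ref = (length >= cfg.min_len_ref_bp) & (ref != "unclassified")
    use_vote = ~use_ref & (length >= cfg.min_len_kmer_bp) & (vote != "unclassified")
    final = np.where(use_ref, ref, np.where(use_vote, vote, "unclassified"))
    decided = np.where(use_ref, "reference", np.where(use_vote, "kmer_vote", "none"))
    out = pd.DataFrame(
        {
            "contig_id": manifest["contig_id"].to_numpy(),
            "final_label": final,
            "decided_by": decided,
        }
    )
    return validate_final_table(out)
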