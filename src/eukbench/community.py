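"""Community-level statistics for drinking-water metagenome surveys.

Downstream of contig classification, four analyses summarize a set of
samples mapped against a coassembly:

* :func:`presence_calls` — a contig (or 18S rRNA gene) is *present* in
  a sample when at least 25% of its bases have a mapped read
  (breadth-of-coverage threshold, inclusive); this damps spurious
  cross-sample mappings of conserved regions.
* :func:`bp_fractions` — per-sample fractions of mapped assembled bp
  attributed to eukaryotes, prokaryotes, viruses and unclassified
  contigs, weighting each present contig by mean depth × length.
* :func:`cluster_samples` — k-means (k=2) on sequencing coverage
  (Nonpareil) and logit-transformed eukaryotic bp fraction, both
  z-scored, splitting samples into *eukaryotic-deficient* and
  *eukaryotic-increasing* groups.
* :func:`cooccurrence_edges` / :func:`detect_modules` — a
  presence–absence co-occurrence network: for each taxon pair a
  one-tailed hypergeometric test of co-presence enrichment (edge when
  p < 0.05, no multiple-testing correction by default), partitioned
  into modules by Leiden modularity maximization; reported modules have
  more than 10 members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "presence_calls",
    "group_labels_from_final",
    "bp_fractions",
    "cluster_samples",
    "cooccurrence_edges",
    "detect_modules",
    "NetworkModule",
]

#: Per-sample groups for bp fractions; ``NA`` collects unclassified contigs.
FRACTION_GROUPS = ("eukaryote", "prokaryote", "virus", "NA")


def presence_calls(cov: pd.DataFrame, breadth_min: float = 0.25) -> pd.DataFrame:
    """Boolean contig × sample presence matrix from coverage breadth.

    A contig is present in a sample iff its breadth of coverage is at
    least ``breadth_min`` (inclusive). Pairs absent from the coverage
    table are absent.
    """
    if not 0 <= breadth_min <= 1:
        raise ValueError("breadth_min must lie in [0, 1]")
    present = cov.assign(present=cov["breadth"] >= breadth_min).pivot_table(
        index="contig_id", columns="sample_id", values="present",
        aggfunc="any", fill_value=False,
    )
    return present.astype(bool)


def group_labels_from_final(
    final_labels: pd.DataFrame, viral_ids: set[str] | None = None
) -> pd.DataFrame:
    """Map hybrid-classifier labels onto the four bp-fraction groups.

    ``eukaryote`` stays; ``noneukaryote`` becomes ``prokaryote`` unless
    the contig id is listed in ``viral_ids`` (e.g. from a viral
    detector); ``unclassified`` becomes ``NA``.
    """
    viral_ids = viral_ids or set()
    lab = final_labels["final_label"].map(
        {"eukaryote": "eukaryote", "noneukaryote": "prokaryote", "unclassified": "NA"}
    )
    lab = lab.mask(final_labels["contig_id"].isin(viral_ids), "virus")
    return pd.DataFrame({"contig_id": final_labels["contig_id"], "group": lab})


def bp_fractions(
    cov: pd.DataFrame,
    lengths: pd.DataFrame,
    groups: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    weighting: str = "depth_length",
) -> pd.DataFrame:
    """Per-sample bp fractions over {eukaryote, prokaryote, virus, NA}.

    Each contig present in a sample contributes mean depth × contig
    length (an estimate of mapped bp; ``weighting="length"`` uses
    assembled length only). Fractions sum to 1 for every sample with at
    least one present contig; samples with none get NaN rows and a
    warning.

    Parameters
    ----------
    cov:
        Coverage table (sample_id, contig_id, mean_depth, breadth).
    lengths:
        DataFrame with contig_id and length_bp (e.g. a manifest).
    groups:
        DataFrame with contig_id and group in {eukaryote, prokaryote,
        virus, NA} (see :func:`group_labels_from_final`).
    presence:
        Presence matrix; computed from ``cov`` at the default threshold
        when omitted.
    """
    if weighting not in ("depth_length", "length"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if presence is None:
        presence = presence_calls(cov)
    grp = groups.set_index("contig_id")["group"]
    missing = set(cov["contig_id"]) - set(grp.index)
    if missing:
        raise ValueError(f"groups missing for contigs: {sorted(missing)[:5]!r}")
    bad = ~grp.isin(FRACTION_GROUPS)
    if bad.any():
        raise ValueError(f"unknown group {grp[bad].iloc[0]!r}")
    length = lengths.set_index("contig_id")["length_bp"]

    df = cov.copy()
    pres_long = presence.stack()
    df["present"] = pres_long.reindex(
        pd.MultiIndex.from_frame(df[["contig_id", "sample_id"]])
    ).to_numpy()
    df = df[df["present"].fillna(False).astype(bool)]
    df["group"] = grp.reindex(df["contig_id"]).to_numpy()
    df["length_bp"] = length.reindex(df["contig_id"]).to_numpy()
    if df["length_bp"].isna().any():
        raise ValueError("coverage table references contigs without lengths")
    if weighting == "depth_length":
        df["weight"] = df["mean_depth"] * df["length_bp"]
    else:
        df["weight"] = df["length_bp"].astype(float)

    samples = sorted(cov["sample_id"].unique())
    table = (
        df.pivot_table(index="sample_id", columns="group", values="weight",
                       aggfunc="sum", fill_value=0.0)
        .reindex(index=samples, columns=list(FRACTION_GROUPS), fill_value=0.0)
    )
    totals = table.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"samples with no present contigs: {list(table.index[empty])!r}; "
            "their fractions are undefined",
            stacklevel=2,
        )
    out = table.div(totals.where(~empty), axis=0)
    out.columns.name = None
    out.index.name = "sample_id"
    return out


def _logit_with_pseudocount(fractions: np.ndarray) -> np.ndarray:
    """logit(f) with zeros replaced by half the smallest nonzero fraction.

    Fractions of exactly 1 are symmetrically pulled in by half the
    smallest nonzero complement so the transform stays finite.
    """
    f = fractions.astype(float).copy()
    nz = f[f > 0]
    if nz.size == 0:
        raise ValueError("all fractions are zero; logit undefined")
    f[f == 0] = nz.min() / 2
    comp = 1 - f
    nzc = comp[comp > 0]
    if nzc.size == 0:
        raise ValueError("all fractions are one; logit undefined")
    f[comp == 0] = 1 - nzc.min() / 2
    return np.log(f / (1 - f))


def cluster_samples(
    samples: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """k-means clustering of samples by coverage and eukaryotic fraction.

    ``samples`` needs columns sample_id, nonpareil_coverage and
    euk_fraction. The eukaryotic fraction is logit-transformed (zeros
    replaced by half the smallest nonzero fraction), both variables are
    z-scored, and k-means with ``n_init`` restarts is run. With k=2 the
    cluster with the lower mean eukaryotic fraction is named
    ``deficient`` and the other ``increasing``; with larger k clusters
    are named ``cluster_0..`` in increasing order of mean eukaryotic
    fraction.
    """
    from sklearn.cluster import KMeans

    df = samples.dropna(subset=["euk_fraction", "nonpareil_coverage"]).copy()
    if len(df) < k:
        raise ValueError(f"need at least k={k} samples with defined fractions")
    x = np.column_stack(
        [
            df["nonpareil_coverage"].to_numpy(dtype=float),
            _logit_with_pseudocount(df["euk_fraction"].to_numpy()),
        ]
    )
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).all():
        warnings.warn("all samples identical; clustering is degenerate", stacklevel=2)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    labels = km.labels_

    order = (
        pd.Series(df["euk_fraction"].to_numpy(), index=labels)
        .groupby(level=0)
        .mean()
        .sort_values()
        .index
    )
    if k == 2:
        names = {order[0]: "deficient", order[1]: "increasing"}
    else:
        names = {c: f"cluster_{rank}" for rank, c in enumerate(order)}
    return pd.DataFrame(
        {"sample_id": df["sample_id"].to_numpy(), "cluster": [names[c] for c in labels]}
    )


def cooccurrence_edges(
    presence: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """One-tailed hypergeometric co-presence tests for all taxon pairs.

    For taxa A and B with prevalences K_A and K_B over N samples and
    co-presence count x, the p-value is P(X >= x) with
    X ~ Hypergeometric(N, K_A, K_B) — the chance of at least x shared
    samples if A's samples were drawn at random. An edge is significant
    when p < ``alpha`` (Benjamini–Hochberg across pairs first when
    ``fdr`` is set; off by default). Taxa present in no sample are
    dropped; self-pairs are never tested.

    Returns a DataFrame (taxon_a, taxon_b, k_a, k_b, co_count,
    n_samples, p_value, significant) over all tested pairs.
    """
    mat = presence.astype(bool)
    n = mat.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mat = mat.loc[mat.any(axis=1)]
    taxa = list(mat.index)
    x = mat.to_numpy().astype(np.int64)
    k = x.sum(axis=1)
    co = x @ x.T
    rows = []
    for i, j in combinations(range(len(taxa)), 2):
        p = float(hypergeom.sf(co[i, j] - 1, n, k[i], k[j]))
        rows.append(
            {
                "taxon_a": taxa[i],
                "taxon_b": taxa[j],
                "k_a": int(k[i]),
                "k_b": int(k[j]),
                "co_count": int(co[i, j]),
                "n_samples": n,
                "p_value": p,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["taxon_a", "taxon_b", "k_a", "k_b", "co_count", "n_samples", "p_value"],
    )
    if edges.empty:
        edges["significant"] = pd.Series(dtype=bool)
        return edges
    if fdr:
        m = len(edges)
        order = np.argsort(edges["p_value"].to_numpy(), kind="stable")
        ranked = edges["p_value"].to_numpy()[order]
        thresh = alpha * (np.arange(1, m + 1)) / m
        passing = ranked <= thresh
        cutoff = ranked[passing].max() if passing.any() else -1.0
        edges["significant"] = edges["p_value"] <= cutoff
    else:
        edges["significant"] = edges["p_value"] < alpha
    return edges


@dataclass(frozen=True)
class NetworkModule:
    """One Leiden module of the significant co-occurrence network."""

    module_id: int
    member_ids: tuple[str, ...]
    n_nodes: int
    n_edges: int


def detect_modules(
    edges: pd.DataFrame,
    min_size: int = 11,
    seed: int = 0,
) -> tuple[list[NetworkModule], pd.DataFrame]:
    """Leiden modularity modules of the significant co-occurrence network.

    Builds an undirected simple graph from the significant edges and
    partitions its nodes by Leiden modularity maximization (seeded).
    Returns the modules with at least ``min_size`` nodes (default 11,
    i.e. more than 10 members) plus the full node→module membership
    table, which partitions all network nodes regardless of module
    size.
    """
    import igraph as ig
    import leidenalg

    sig = edges[edges["significant"]] if "significant" in edges.columns else edges
    if sig.empty:
        return [], pd.DataFrame(columns=["node", "module_id"])
    nodes = sorted(set(sig["taxon_a"]) | set(sig["taxon_b"]))
    index = {v: i for i, v in enumerate(nodes)}
    pairs = {
        tuple(sorted((index[a], index[b])))
        for a, b in zip(sig["taxon_a"], sig["taxon_b"])
        if a != b
    }
    g = ig.Graph(n=len(nodes), edges=sorted(pairs), directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=seed, n_iterations=-1
    )
    membership = pd.DataFrame(
        {"node": nodes, "module_id": list(part.membership)}
    )
    modules = []
    for mid, members in membership.groupby("module_id")["node"]:
        member_set = set(members)
        if len(member_set) < min_size:
            continue
        n_edges = sum(
            1 for a, b in pairs if nodes[a] in member_set and nodes[b] in member_set
        )
        modules.append(
            NetworkModule(
                module_id=int(mid),
                member_ids=tuple(sorted(member_set)),
                n_nodes=len(member_set),
                n_edges=n_edges,
            )
        )
    modules.sort(key=lambda m: (-m.n_nodes, m.module_id))
    return modules, membership
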