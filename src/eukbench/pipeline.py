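"""End-to-end synthetic workflow: simulate → classify → benchmark → community.

One call, one seed, one output directory. The stages mirror a full
benchmark study: a genome catalog is simulated, mock-metagenome
compositions are drawn, test contigs extracted, classifier calls
emulated, the hybrid ensemble applied, classification scored under the
ratio-subsampling protocol, synthetic bins scored with the bin-quality
metrics, and community statistics (fractions, clustering, network
modules) computed on a simulated coverage table. All reports are JSON
and TSV; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bench_binning, bench_classify, community, ensemble, io_formats, mocksim

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Problem sizes for the end-to-end synthetic workflow."""

    n_euk_genomes: int = 8
    n_prok_genomes: int = 40
    n_samples: int = 15
    fragment_lengths: tuple[int, ...] = (1000, 3000, 5000)
    n_fragments_per_genome: int = 30
    target_ratio: float = 0.05
    n_repeats: int = 100
    min_len_ref_bp: int = 1000
    min_len_kmer_bp: int = 3000
    breadth_min: float = 0.25


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def _simulate_coverage(
    manifest: pd.DataFrame,
    n_samples: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-sample coverage with eukaryote depth suppressed in half the samples.

    The first half of the samples emulate eukaryote-poor communities
    (deep prokaryote coverage, shallow eukaryote coverage); the second
    half eukaryote-rich ones. Breadth saturates with depth, so shallow
    contigs fall below the presence threshold.
    """
    is_euk = (manifest["true_label"] == "eukaryote").to_numpy()
    frames = []
    for s in range(n_samples):
        rich = s >= n_samples // 2
        euk_mean = 2.0 if rich else 0.1
        depth = np.where(
            is_euk,
            rng.lognormal(np.log(euk_mean), 0.8, len(manifest)),
            rng.lognormal(np.log(3.0), 0.8, len(manifest)),
        )
        # breadth rises quickly with depth (Poisson-coverage style)
        breadth = np.clip(1 - np.exp(-depth * rng.uniform(0.8, 1.2, len(manifest))), 0, 1)
        breadth[depth < 0.02] = 0.0
        depth = np.where(breadth == 0, 0.0, depth)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"sample_{s:02d}",
                    "contig_id": manifest["contig_id"].to_numpy(),
                    "mean_depth": depth,
                    "breadth": breadth,
                    "nonpareil_coverage": float(
                        np.clip(rng.normal(0.85 if rich else 0.6, 0.05), 0, 1)
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    seed: int,
    out_dir: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run the full synthetic workflow; returns the summary report dict.

    Writes composition.tsv, manifest.tsv, calls.tsv, final_labels.tsv,
    classification.json, binning.json, community.json and summary.json
    under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(8)]

    # 1. catalog and compositions
    catalog = mocksim.random_catalog(
        n_euk=cfg.n_euk_genomes, n_prok=cfg.n_prok_genomes, seed=seeds[0]
    )
    comp = mocksim.sample_composition(
        catalog,
        mocksim.CompositionConfig(n_samples=cfg.n_samples, seed=seeds[1]),
    )
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)
    euk_share = (
        comp[comp["superkingdom"] == "eukaryote"].groupby("sample_id")["bp_share"].sum()
    )

    # 2. test contigs and emulated classifier calls
    manifest = mocksim.extract_test_contigs(
        catalog,
        lengths=cfg.fragment_lengths,
        n_per_genome=cfg.n_fragments_per_genome,
        seed=seeds[2],
    )
    io_formats.write_contig_manifest(manifest, out / "manifest.tsv")
    profiles = mocksim.default_profiles()
    calls = mocksim.simulate_calls(manifest, profiles, seed=seeds[3])
    io_formats.write_call_table(calls, out / "calls.tsv")

    # 3. hybrid ensemble classification
    ens_cfg = ensemble.EnsembleConfig(
        min_len_ref_bp=cfg.min_len_ref_bp, min_len_kmer_bp=cfg.min_len_kmer_bp
    )
    final = ensemble.classify_assembly(manifest, calls, ens_cfg)
    io_formats.write_final_table(final, out / "final_labels.tsv")

    # 4. classification benchmark: ensemble vs each single tool
    classification: dict = {}
    results = {}
    results["ensemble"] = bench_classify.evaluate(
        final, manifest, cfg.target_ratio, cfg.n_repeats, seed=seeds[4]
    )
    for profile in profiles:
        single = calls[calls["tool_id"] == profile.tool_id]
        pred = pd.DataFrame(
            {
                "contig_id": single["contig_id"],
                "final_label": single["norm_label"],
                "decided_by": np.where(
                    single["norm_label"] == "unclassified", "none", "kmer_vote"
                ),
            }
        )
        results[profile.tool_id] = bench_classify.evaluate(
            pred, manifest, cfg.target_ratio, cfg.n_repeats, seed=seeds[4]
        )
    classification = {name: r.summary() for name, r in results.items()}
    _dump_json(classification, out / "classification.json")

    # 5. binning benchmark on synthetic bins over the gold map
    goldmap = pd.DataFrame(
        {
            "contig_id": manifest["contig_id"],
            "source_genome_id": manifest["source_genome_id"],
            "genome_superkingdom": manifest["true_label"],
            "length_bp": manifest["length_bp"],
        }
    )
    keep = bench_binning.strategy_filter(
        manifest, final, "OTHER_rem", min_len=cfg.min_len_ref_bp
    )
    gold_f = goldmap[goldmap["contig_id"].isin(keep)].reset_index(drop=True)
    bins = mocksim.simulate_bins(gold_f, seed=seeds[5])
    scores, f1_summary = bench_binning.purity_completeness_f1(bins, gold_f)
    binning = {
        "strategy": "OTHER_rem",
        "n_contigs": int(len(gold_f)),
        "pct_euk_bp_binned": bench_binning.pct_euk_bp_binned(bins, gold_f),
        "ari": bench_binning.ari(bins, gold_f),
        "f1": f1_summary,
    }
    _dump_json(binning, out / "binning.json")

    # 6. community statistics on a simulated coverage table
    rng = np.random.default_rng(seeds[6])
    cov = _simulate_coverage(manifest, cfg.n_samples, rng)
    presence = community.presence_calls(cov, cfg.breadth_min)
    groups = community.group_labels_from_final(final)
    fractions = community.bp_fractions(cov, manifest, groups, presence)
    nonpareil = cov.groupby("sample_id")["nonpareil_coverage"].first()
    sample_table = pd.DataFrame(
        {
            "sample_id": fractions.index,
            "nonpareil_coverage": nonpareil.reindex(fractions.index).to_numpy(),
            "euk_fraction": fractions["eukaryote"].to_numpy(),
        }
    )
    clusters = community.cluster_samples(sample_table, seed=seeds[7])
    euk_contigs = final.loc[final["final_label"] == "eukaryote", "contig_id"]
    sub = presence.loc[presence.index.intersection(euk_contigs)]
    # pairwise tests only over informative contigs (present in some but
    # not all samples), capped for tractability
    prevalence = sub.sum(axis=1)
    informative = (prevalence >= 2) & (prevalence <= sub.shape[1] - 1)
    sub = sub.loc[sorted(sub.index[informative])[:120]]
    edges = community.cooccurrence_edges(sub)
    modules, membership = community.detect_modules(edges, seed=seeds[7])
    communities = {
        "fractions": {
            s: {g: (None if pd.isna(v) else float(v)) for g, v in row.items()}
            for s, row in fractions.iterrows()
        },
        "clusters": dict(zip(clusters["sample_id"], clusters["cluster"])),
        "n_significant_edges": int(edges["significant"].sum()),
        "n_tested_pairs": int(len(edges)),
        "modules": [
            {"module_id": m.module_id, "n_nodes": m.n_nodes, "n_edges": m.n_edges}
            for m in modules
        ],
    }
    _dump_json(communities, out / "community.json")

    summary = {
        "seed": seed,
        "n_genomes": {"eukaryote": cfg.n_euk_genomes, "prokaryote": cfg.n_prok_genomes},
        "n_test_contigs": int(len(manifest)),
        "composition_euk_bp_share_mean": float(euk_share.mean()),
        "classification": classification,
        "binning": binning,
        "community": {
            k: communities[k]
            for k in ("clusters", "n_significant_edges", "n_tested_pairs", "modules")
        },
    }
    _dump_json(summary, out / "summary.json")
    return summary
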