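"""Benchmark emulated classifiers under realistic class imbalance.

Simulates 6,000 test contigs, emulates three noisy k-mer classifiers,
and compares each single tool with their majority vote using the
ratio-subsampled protocol: the contig set is repeatedly subsampled to a
eukaryote:prokaryote bp ratio of 0.05 and scored with MCC, precision
and recall (mean ± sd over 100 subsamples).
"""

import numpy as np
import pandas as pd

from eukbench import EnsembleConfig, classify_assembly, mocksim
from eukbench.bench_classify import evaluate

rng = np.random.default_rng(0)
n = 6000
manifest = pd.DataFrame(
    {
        "contig_id": [f"c{i}" for i in range(n)],
        "length_bp": rng.choice([1000, 3000, 5000], size=n),
        "true_label": np.where(rng.random(n) < 0.5, "eukaryote", "prokaryote"),
        "source_genome_id": "g",
    }
)
profiles = [
    mocksim.flat_profile("tool_a", 0.90, 0.90),
    mocksim.flat_profile("tool_b", 0.85, 0.93),
    mocksim.flat_profile("tool_c", 0.88, 0.88),
]
calls = mocksim.simulate_calls(manifest, profiles, seed=1)

cfg = EnsembleConfig(
    kmer_tools=("tool_a", "tool_b", "tool_c"),
    ref_tool="none_available",
    min_len_ref_bp=1000,
    min_len_kmer_bp=1000,
)
final = classify_assembly(manifest, calls, cfg)

print(f"{'classifier':<16}{'MCC':>14}{'precision':>14}{'recall':>14}")
for tool in ("tool_a", "tool_b", "tool_c"):
    sub = calls[calls["tool_id"] == tool]
    pred = pd.DataFrame(
        {
            "contig_id": sub["contig_id"],
            "final_label": sub["norm_label"],
            "decided_by": np.where(sub["norm_label"] == "unclassified", "none", "kmer_vote"),
        }
    )
    r = evaluate(pred, manifest, n_repeats=100, seed=2)
    print(
        f"{tool:<16}"
        f"{r.mean['mcc']:>8.3f}±{r.sd['mcc']:.3f}"
        f"{r.mean['precision']:>8.3f}±{r.sd['precision']:.3f}"
        f"{r.mean['recall']:>8.3f}±{r.sd['recall']:.3f}"
    )
r = evaluate(final, manifest, n_repeats=100, seed=2)
print(
    f"{'majority vote':<16}"
    f"{r.mean['mcc']:>8.3f}±{r.sd['mcc']:.3f}"
    f"{r.mean['precision']:>8.3f}±{r.sd['precision']:.3f}"
    f"{r.mean['recall']:>8.3f}±{r.sd['recall']:.3f}"
)
print(
    "\nAt a 0.05 bp ratio false positives dominate precision; the"
    "\nmajority vote suppresses uncorrelated errors and lifts MCC above"
    "\nevery individual tool."
)
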