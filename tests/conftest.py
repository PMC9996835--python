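import numpy as np
import pandas as pd
import pytest

from eukbench import mocksim


@pytest.fixture
def small_catalog() -> mocksim.GenomeCatalog:
    return mocksim.GenomeCatalog(
        (
            mocksim.Genome("euk_a", "eukaryote", (20_000, 50_000)),
            mocksim.Genome("euk_b", "eukaryote", (80_000,)),
            mocksim.Genome("prok_a", "prokaryote", (30_000, 10_000)),
            mocksim.Genome("prok_b", "prokaryote", (40_000,)),
            mocksim.Genome("prok_c", "prokaryote", (25_000,)),
        )
    )


def random_manifest(
    n: int,
    rng: np.random.Generator,
    lengths=(500, 1000, 2000, 3000, 5000),
    p_euk: float = 0.5,
) -> pd.DataFrame:
    labels = np.where(rng.random(n) < p_euk, "eukaryote", "prokaryote")
    return pd.DataFrame(
        {
            "contig_id": [f"c{i:05d}" for i in range(n)],
            "length_bp": rng.choice(lengths, size=n),
            "true_label": labels,
            "source_genome_id": np.where(labels == "eukaryote", "gE", "gP"),
        }
    )


def final_from_labels(contig_ids, labels) -> pd.DataFrame:
    labels = np.asarray(labels, dtype=object)
    return pd.DataFrame(
        {
            "contig_id": np.asarray(contig_ids),
            "final_label": labels,
            "decided_by": np.where(labels == "unclassified", "none", "kmer_vote"),
        }
    )
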