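"""Tabular I/O and label normalization.

Every table the toolkit touches is a UTF-8, tab-separated file with a
header row; empty fields are written as ``"."``. In memory each table is
a plain :class:`pandas.DataFrame` with a fixed column contract, validated
on read.

Heterogeneous classifier outputs (Tiara, Whokaryote, DeepMicrobeFinder,
Kaiju, CAT, or the toolkit's own normalized table) are collapsed onto a
single three-way label vocabulary ``{eukaryote, noneukaryote,
unclassified}``: the task is binary eukaryote identification, so the
multi-class outputs of individual tools (bacteria, archaea, organelle,
virus, plasmid ...) all map to ``noneukaryote`` through per-dialect label
maps. The maps are plain dictionaries and can be edited or replaced at
call time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

#: Normalized classifier-call vocabulary.
NORM_LABELS = ("eukaryote", "noneukaryote", "unclassified")

#: Ground-truth superkingdom vocabulary for benchmark manifests.
TRUE_LABELS = ("eukaryote", "prokaryote", "virus", "unknown")

#: Written for empty fields in TSV output; read back as empty string.
EMPTY_FIELD = "."

MANIFEST_COLUMNS = ["contig_id", "length_bp", "true_label", "source_genome_id"]
CALL_COLUMNS = ["contig_id", "tool_id", "raw_label", "norm_label"]
GOLD_COLUMNS = ["contig_id", "source_genome_id", "genome_superkingdom", "length_bp"]
BIN_COLUMNS = ["contig_id", "bin_id"]
FINAL_COLUMNS = ["contig_id", "final_label", "decided_by"]
COVERAGE_COLUMNS = ["sample_id", "contig_id", "mean_depth", "breadth"]

#: ``bin_id`` value marking a contig left out of every bin.
UNBINNED = "unbinned"


class TableFormatError(ValueError):
    """A TSV did not match its declared column/label contract."""


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise TableFormatError(f"{path}: malformed TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df.replace(EMPTY_FIELD, "")


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].replace("", EMPTY_FIELD)
    out.to_csv(path, sep="\t", index=False)


def _parse_positive_int(series: pd.Series, path: Path, col: str) -> pd.Series:
    try:
        values = pd.to_numeric(series, errors="raise")
    except (ValueError, TypeError) as exc:
        bad = series[pd.to_numeric(series, errors="coerce").isna()]
        line = bad.index[0] + 2  # header + 1-based
        raise TableFormatError(f"{path}: line {line}: non-integer {col!r}") from exc
    values = values.astype("int64")
    if (values < 1).any():
        line = values.index[values < 1][0] + 2
        raise TableFormatError(f"{path}: line {line}: {col} must be >= 1")
    return values


# ---------------------------------------------------------------------------
# contig manifests
# ---------------------------------------------------------------------------

def validate_contig_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a contig manifest DataFrame in place.

    Enforces unique ``contig_id``, positive integer ``length_bp``,
    ``true_label`` in the superkingdom vocabulary, and a non-empty
    ``source_genome_id`` for every labelled benchmark contig.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"manifest missing columns {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    dup = df["contig_id"].duplicated()
    if dup.any():
        raise TableFormatError(
            f"duplicate contig_id: {df.loc[dup, 'contig_id'].iloc[0]!r}"
        )
    if not df["length_bp"].map(lambda v: int(v) == v and v >= 1).all():
        raise TableFormatError("length_bp must be positive integers")
    df["length_bp"] = df["length_bp"].astype("int64")
    bad = ~df["true_label"].isin(TRUE_LABELS)
    if bad.any():
        raise TableFormatError(
            f"unknown true_label {df.loc[bad, 'true_label'].iloc[0]!r}"
        )
    labelled = df["true_label"] != "unknown"
    if (labelled & (df["source_genome_id"] == "")).any():
        raise TableFormatError(
            "benchmark contigs with a known true_label need a source_genome_id"
        )
    return df.reset_index(drop=True)


def read_contig_manifest(path: str | Path) -> pd.DataFrame:
    """Read a contig manifest TSV: contig_id, length_bp, true_label, source_genome_id."""
    path = Path(path)
    df = _read_tsv(path, MANIFEST_COLUMNS)
    df["length_bp"] = _parse_positive_int(df["length_bp"], path, "length_bp")
    try:
        return validate_contig_manifest(df)
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_contig_manifest(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_contig_manifest(df), path)


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

def validate_call_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"call table missing columns {missing}")
    df = df[CALL_COLUMNS].copy()
    dup = df.duplicated(subset=["contig_id", "tool_id"])
    if dup.any():
        pair = df.loc[dup, ["contig_id", "tool_id"]].iloc[0]
        raise TableFormatError(
            f"duplicate (contig_id, tool_id) pair: {tuple(pair)!r}"
        )
    bad = ~df["norm_label"].isin(NORM_LABELS)
    if bad.any():
        raise TableFormatError(
            f"norm_label outside vocabulary: {df.loc[bad, 'norm_label'].iloc[0]!r}"
        )
    return df.reset_index(drop=True)


def read_call_table(path: str | Path) -> pd.DataFrame:
    """Read an already-normalized call table (contig_id, tool_id, raw_label, norm_label)."""
    try:
        return validate_call_table(_read_tsv(path, CALL_COLUMNS))
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_call_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_call_table(df), path)


# ---------------------------------------------------------------------------
# final label tables
# ---------------------------------------------------------------------------

def validate_final_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FINAL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"final label table missing columns {missing}")
    df = df[FINAL_COLUMNS].copy()
    if df["contig_id"].duplicated().any():
        raise TableFormatError("duplicate contig_id in final label table")
    if not df["final_label"].isin(NORM_LABELS).all():
        raise TableFormatError("final_label outside vocabulary")
    if not df["decided_by"].isin(["reference", "kmer_vote", "none"]).all():
        raise TableFormatError("decided_by outside {reference, kmer_vote, none}")
    none_iff_uncl = (df["decided_by"] == "none") == (df["final_label"] == "unclassified")
    if not none_iff_uncl.all():
        raise TableFormatError("decided_by=none must coincide with final_label=unclassified")
    return df.reset_index(drop=True)


def read_final_table(path: str | Path) -> pd.DataFrame:
    try:
        return validate_final_table(_read_tsv(path, FINAL_COLUMNS))
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_final_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_final_table(df), path)


# ---------------------------------------------------------------------------
# gold / bin maps
# ---------------------------------------------------------------------------

def read_gold_map(path: str | Path) -> pd.DataFrame:
    """Gold-standard contig→genome map with superkingdom and bp length."""
    path = Path(path)
    df = _read_tsv(path, GOLD_COLUMNS)[GOLD_COLUMNS]
    df["length_bp"] = _parse_positive_int(df["length_bp"], path, "length_bp")
    if df["contig_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate contig_id in gold map")
    bad = ~df["genome_superkingdom"].isin(TRUE_LABELS)
    if bad.any():
        raise TableFormatError(f"{path}: unknown genome_superkingdom")
    return df.reset_index(drop=True)


def write_gold_map(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[GOLD_COLUMNS], path)


def read_bin_map(path: str | Path) -> pd.DataFrame:
    """Contig→bin map; ``bin_id`` equal to ``unbinned`` (or empty) marks unbinned contigs."""
    df = _read_tsv(path, BIN_COLUMNS)[BIN_COLUMNS]
    if df["contig_id"].duplicated().any():
        raise TableFormatError(f"{path}: a contig may belong to at most one bin")
    df.loc[df["bin_id"] == "", "bin_id"] = UNBINNED
    return df.reset_index(drop=True)


def write_bin_map(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[BIN_COLUMNS], path)


# ---------------------------------------------------------------------------
# per-sample coverage tables
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Per-sample per-contig mean depth and breadth of coverage.

    An optional ``nonpareil_coverage`` column carries the per-sample
    scalar; it must be constant within a sample.
    """
    path = Path(path)
    df = _read_tsv(path, COVERAGE_COLUMNS)
    for col in ("mean_depth", "breadth"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if "nonpareil_coverage" in df.columns:
        df["nonpareil_coverage"] = pd.to_numeric(df["nonpareil_coverage"]).astype(float)
    if df.duplicated(subset=["sample_id", "contig_id"]).any():
        raise TableFormatError(f"{path}: duplicate (sample_id, contig_id)")
    if ((df["breadth"] < 0) | (df["breadth"] > 1)).any():
        raise TableFormatError(f"{path}: breadth must lie in [0, 1]")
    if (df["mean_depth"] < 0).any():
        raise TableFormatError(f"{path}: mean_depth must be >= 0")
    if ((df["breadth"] > 0) & (df["mean_depth"] <= 0)).any():
        raise TableFormatError(f"{path}: breadth > 0 requires mean_depth > 0")
    return df.reset_index(drop=True)


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------

def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Boolean taxa × samples matrix; first column names the taxon/contig."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_presence_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.astype(int).to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# classifier-output dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """How to turn one tool's native output into (contig_id, raw_label) rows.

    ``reader`` extracts the raw rows; ``label_map`` then maps each raw
    label to the normalized vocabulary. With ``match="substring"`` a map
    key only needs to occur inside the raw label (lineage strings). Raw
    labels not covered by the map become ``unclassified`` with a warning.
    """

    name: str
    reader: Callable[[Path], pd.DataFrame]
    label_map: Mapping[str, str]
    match: str = "exact"  # or "substring"
    default_tool_id: str = ""


def _reader_tiara(path: Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sequence_id", "class_fst_stage"])
    return pd.DataFrame(
        {"contig_id": df["sequence_id"], "raw_label": df["class_fst_stage"].str.strip()}
    )


def _reader_whokaryote(path: Path) -> pd.DataFrame:
    df = _read_tsv(path, ["contig", "predicted"])
    return pd.DataFrame({"contig_id": df["contig"], "raw_label": df["predicted"].str.strip()})


def _reader_deepmicrobefinder(path: Path) -> pd.DataFrame:
    # score table: one column per class, highest score wins
    df = pd.read_csv(path, sep="\t")
    name_col = df.columns[0]
    score_cols = [c for c in df.columns[1:]]
    raw = df[score_cols].astype(float).idxmax(axis=1)
    return pd.DataFrame({"contig_id": df[name_col].astype(str), "raw_label": raw})


def _reader_kaiju(path: Path) -> pd.DataFrame:
    # headerless: status (C/U), sequence id, taxon id, [..., taxon name last]
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise TableFormatError(f"{path}: kaiju output needs >= 3 columns")
    status = df[0].str.strip()
    names = df[df.columns[-1]] if df.shape[1] > 3 else pd.Series([""] * len(df))
    raw = names.where(status == "C", other="__unclassified__")
    return pd.DataFrame({"contig_id": df[1], "raw_label": raw})


def _reader_cat(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("# ").strip() for c in df.columns]
    if "contig" not in df.columns or "superkingdom" not in df.columns:
        raise TableFormatError(f"{path}: CAT table needs '# contig' and 'superkingdom'")
    # CAT appends a support score, e.g. "Bacteria: 0.97"
    raw = df["superkingdom"].str.split(":").str[0].str.strip()
    return pd.DataFrame({"contig_id": df["contig"], "raw_label": raw})


def _reader_normalized(path: Path) -> pd.DataFrame:
    df = _read_tsv(path, ["contig_id", "raw_label"])
    out = pd.DataFrame({"contig_id": df["contig_id"], "raw_label": df["raw_label"]})
    if "tool_id" in df.columns:
        out["tool_id"] = df["tool_id"]
    return out


#: Built-in dialects keyed by name. ``label_map`` values are editable:
#: ``dict(DIALECTS["cat"].label_map)`` gives a copy to customize.
DIALECTS: dict[str, Dialect] = {
    "tiara": Dialect(
        name="tiara",
        reader=_reader_tiara,
        label_map={
            "eukarya": "eukaryote",
            "bacteria": "noneukaryote",
            "archaea": "noneukaryote",
            "prokarya": "noneukaryote",
            "organelle": "noneukaryote",
            "mitochondrion": "noneukaryote",
            "plastid": "noneukaryote",
            "unknown": "unclassified",
        },
        default_tool_id="tiara",
    ),
    "whokaryote": Dialect(
        name="whokaryote",
        reader=_reader_whokaryote,
        label_map={"eukaryote": "eukaryote", "prokaryote": "noneukaryote"},
        default_tool_id="whokaryote",
    ),
    "deepmicrobefinder": Dialect(
        name="deepmicrobefinder",
        reader=_reader_deepmicrobefinder,
        label_map={
            "Eukaryote": "eukaryote",
            "EukaryoteVirus": "noneukaryote",
            "Prokaryote": "noneukaryote",
            "ProkaryoteVirus": "noneukaryote",
            "Plasmid": "noneukaryote",
        },
        default_tool_id="deepmicrobefinder",
    ),
    "kaiju": Dialect(
        name="kaiju",
        reader=_reader_kaiju,
        label_map={
            "__unclassified__": "unclassified",
            "Eukaryota": "eukaryote",
            "Bacteria": "noneukaryote",
            "Archaea": "noneukaryote",
            "Viruses": "noneukaryote",
        },
        match="substring",
        default_tool_id="kaiju",
    ),
    "cat": Dialect(
        name="cat",
        reader=_reader_cat,
        label_map={
            "Eukaryota": "eukaryote",
            "Bacteria": "noneukaryote",
            "Archaea": "noneukaryote",
            "Viruses": "noneukaryote",
            "no support": "unclassified",
            "NA": "unclassified",
        },
        default_tool_id="cat",
    ),
    "normalized": Dialect(
        name="normalized",
        reader=_reader_normalized,
        label_map={
            "eukaryote": "eukaryote",
            "noneukaryote": "noneukaryote",
            "unclassified": "unclassified",
        },
        default_tool_id="normalized",
    ),
}


def apply_label_map(
    raw_labels: pd.Series, label_map: Mapping[str, str], match: str = "exact"
) -> pd.Series:
    """Map raw tool labels to the normalized vocabulary.

    Unmapped labels become ``unclassified`` and trigger one warning
    listing the distinct offending labels; no row is ever dropped.
    """
    if match == "exact":
        norm = raw_labels.map(label_map)
    elif match == "substring":
        def lookup(value: str) -> str | None:
            for key, target in label_map.items():
                if key in value:
                    return target
            return None

        norm = raw_labels.map(lookup)
    else:
        raise ValueError(f"unknown match mode {match!r}")
    unmapped = norm.isna()
    if unmapped.any():
        labels = sorted(set(raw_labels[unmapped]))
        warnings.warn(
            f"{int(unmapped.sum())} rows with unmapped labels {labels!r} "
            "set to 'unclassified'",
            stacklevel=2,
        )
        norm = norm.fillna("unclassified")
    bad = ~norm.isin(NORM_LABELS)
    if bad.any():
        raise TableFormatError(
            f"label map targets outside vocabulary: {sorted(set(norm[bad]))!r}"
        )
    return norm


def normalize_calls(
    raw_table: str | Path,
    dialect: str | Dialect,
    tool_id: str | None = None,
    label_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse one tool's output file into a normalized call table.

    Parameters
    ----------
    raw_table:
        Path to the tool's native output.
    dialect:
        Name of a built-in dialect or a custom :class:`Dialect`.
    tool_id:
        Overrides the dialect's default tool id in the output.
    label_map:
        Overrides the dialect's label map (e.g. to change how CAT
        lineages below superkingdom are collapsed).
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; available: {sorted(DIALECTS)}"
            ) from None
    raw = dialect.reader(Path(raw_table))
    norm = apply_label_map(
        raw["raw_label"].astype(str), label_map or dialect.label_map, dialect.match
    )
    out = pd.DataFrame(
        {
            "contig_id": raw["contig_id"].astype(str),
            "tool_id": tool_id or raw.get("tool_id", dialect.default_tool_id),
            "raw_label": raw["raw_label"].astype(str),
            "norm_label": norm,
        }
    )
    return validate_call_table(out)
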