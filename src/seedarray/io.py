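"""Readers and writers for the pipeline's interchange formats.

Tab-delimited tables with a header row carry all matrices (the
supplementary-table idiom); FASTA carries sequences; Newick carries
dendrograms; YAML or JSON carries configuration.  Reads validate the
documented column contracts and round-trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPARISON_COLUMNS = ["probe_set_id", "cross", "comparison_index", "slr", "p"]
DETECTION_COLUMNS = ["probe_set_id", "array", "detection_p"]
DYESWAP_COLUMNS = ["probe_id", "cross", "array_index", "dye_orientation", "cy3", "cy5"]
SUMMARY_COLUMNS = ["at_id", "cross", "avg_pslr", "avg_slr_agilent", "present"]
PAIR_COLUMNS = ["probe_set_id", "probe_id", "at_id", "q", "strand"]
GENE_MAP_COLUMNS = ["at_id", "probe_set_id", "probe_id"]


class TableFormatError(ValueError):
    """A table file violates its column contract."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees float round-trip through the text format
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path, required_columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_comparisons(path: str | Path) -> pd.DataFrame:
    return read_table(path, COMPARISON_COLUMNS)


def read_detection(path: str | Path) -> pd.DataFrame:
    return read_table(path, DETECTION_COLUMNS)


def read_dyeswap(path: str | Path) -> pd.DataFrame:
    return read_table(path, DYESWAP_COLUMNS)


def read_summary(path: str | Path) -> pd.DataFrame:
    return read_table(path, SUMMARY_COLUMNS)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    return read_table(path, GENE_MAP_COLUMNS)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an id -> sequence mapping; sequences uppercased on read."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise TableFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_config(path: str | Path) -> dict:
    """YAML or JSON configuration; the format is chosen by suffix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(config: Mapping, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(dict(config), indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(config), sort_keys=True))


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_pairs(pairs, path: str | Path) -> None:
    """Correspondence pairs as TSV (probe_set_id, probe_id, at_id, Q, strand)."""
    df = pd.DataFrame(
        [(p.probe_set_id, p.probe_id, p.at_id, p.q, p.strand) for p in pairs],
        columns=PAIR_COLUMNS,
    )
    write_table(df, path)
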