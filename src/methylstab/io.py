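"""Plain-text round-trip helpers: FASTA, window BED, count/sample/shell TSVs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CountMatrix


def write_fasta(contigs: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """BED4+1: contig, start, end, window_id, cpg_count (when present)."""
    cols = ["contig", "start", "end", "window_id"]
    if "cpg_count" in windows:
        cols.append("cpg_count")
    windows[cols].to_csv(path, sep="\t", header=False, index=False)


def read_windows_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["contig", "start", "end", "window_id", "cpg_count"][: df.shape[1]]
    df.columns = names
    return df


def write_count_matrix(cm: CountMatrix, prefix) -> None:
    """TSV trio: counts (window_id + sample columns), sample sheet, windows."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
    sheet = cm.samples.copy()
    sheet["library_size"] = cm.library_size.loc[sheet["sample"]].to_numpy()
    sheet.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)
    cm.windows.to_csv(f"{prefix}.windows.tsv", sep="\t", index=False)


def read_count_matrix(prefix) -> CountMatrix:
    counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t", index_col="window_id")
    sheet = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    windows = pd.read_csv(f"{prefix}.windows.tsv", sep="\t")
    lib = pd.Series(
        sheet["library_size"].to_numpy(), index=sheet["sample"], name="library_size"
    )
    return CountMatrix(
        counts=counts,
        samples=sheet.drop(columns=["library_size"]),
        library_size=lib,
        windows=windows,
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
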