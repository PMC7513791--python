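"""Fixed-width window grids over a reference, fragment counting, and RPKM.

Coordinates are 0-based half-open (BED convention) throughout.  Trailing
sub-window remainders of each contig are dropped so every retained window has
identical length.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import CountMatrix

__all__ = [
    "make_windows",
    "cpg_density",
    "count_fragments",
    "rpkm_normalize",
    "filter_windows",
    "read_fragment_bed",
]


class InputError(ValueError):
    pass


def _load_sequences(reference) -> dict[str, str]:
    """Accept a contig->sequence mapping or a FASTA path."""
    if isinstance(reference, Mapping):
        return dict(reference)
    from pyfaidx import Fasta

    path = Path(reference)
    if not path.exists():
        raise InputError(f"FASTA not found: {path}")
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=False)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    if not seqs:
        raise InputError(f"FASTA has no sequences: {path}")
    return seqs


def make_windows(reference, window_size: int = 100) -> pd.DataFrame:
    """Tile each contig into fixed windows, dropping the trailing remainder.

    Windows are ordered by (contig appearance order, start) and numbered with
    a global integer window_id.
    """
    if window_size < 1:
        raise InputError("window_size must be positive")
    seqs = _load_sequences(reference)
    if not seqs:
        raise InputError("reference is empty")
    rows = []
    window_id = 0
    for contig, seq in seqs.items():
        n = len(seq) // window_size
        for w in range(n):
            start = w * window_size
            rows.append((contig, start, start + window_size, window_id))
            window_id += 1
    return pd.DataFrame(rows, columns=["contig", "start", "end", "window_id"])


def cpg_density(windows: pd.DataFrame, reference) -> pd.DataFrame:
    """Count CG dinucleotides per window, first-base-in-window rule.

    A CG whose C is the last base of a window is credited to that window even
    though its G lies in the next; case-insensitive; ambiguity codes never
    match.
    """
    seqs = _load_sequences(reference)
    windows = windows.reset_index(drop=True)
    out = windows.copy()
    counts = np.zeros(len(windows), dtype=int)
    for contig, grp in windows.groupby("contig", sort=False):
        if contig not in seqs:
            raise InputError(f"contig {contig!r} missing from reference")
        s = np.frombuffer(seqs[contig].upper().encode("ascii"), dtype="S1")
        if len(grp) and grp["end"].max() > len(s):
            raise InputError(
                f"window beyond end of contig {contig!r} "
                f"({grp['end'].max()} > {len(s)})"
            )
        is_cg_start = np.zeros(len(s), dtype=np.int64)
        if len(s) > 1:
            is_cg_start[:-1] = (s[:-1] == b"C") & (s[1:] == b"G")
        cum = np.concatenate([[0], np.cumsum(is_cg_start)])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        counts[grp.index.to_numpy()] = cum[ends] - cum[starts]
    out["cpg_count"] = counts
    return out


def read_fragment_bed(path) -> pd.DataFrame:
    """Parse a minimal fragment BED (contig, start, end); errors cite lines."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end < start:
                raise InputError(f"{path}:{lineno}: invalid interval")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def count_fragments(
    fragments: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """Assign each fragment to one window by the midpoint rule.

    midpoint = floor((start + end) / 2); fragments whose midpoint falls in a
    dropped trailing remainder (or on an unknown contig) are discarded.
    library_size records *all* input fragments per sample, so assigned +
    discarded = input.
    """
    if not fragments:
        raise InputError("no fragment sets supplied")
    window_size = int((windows["end"] - windows["start"]).iloc[0])
    # per-contig number of windows and window_id of the first window
    per_contig = {}
    for contig, grp in windows.groupby("contig", sort=False):
        ids = grp.sort_values("start")["window_id"].to_numpy()
        per_contig[contig] = ids

    names = list(fragments)
    mat = np.zeros((len(windows), len(names)), dtype=int)
    wid_to_row = pd.Series(
        np.arange(len(windows)), index=windows["window_id"].to_numpy()
    )
    lib = {}
    for j, name in enumerate(names):
        bed = fragments[name]
        lib[name] = len(bed)
        for contig, grp in bed.groupby("contig", sort=False):
            if contig not in per_contig:
                continue  # discarded: contig has no windows
            ids = per_contig[contig]
            mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            idx = mids // window_size
            ok = (idx >= 0) & (idx < len(ids))
            hit, cnt = np.unique(idx[ok], return_counts=True)
            mat[wid_to_row.loc[ids[hit]].to_numpy(), j] += cnt

    counts = pd.DataFrame(
        mat, index=windows["window_id"].to_numpy(), columns=names
    )
    counts.index.name = "window_id"
    if samples is None:
        samples = pd.DataFrame(
            {"sample": names, "population": names,
             "habitat": ["" for _ in names],
             "generation": ["" for _ in names],
             "n_individuals": [0 for _ in names]}
        )
    return CountMatrix(
        counts=counts,
        samples=samples.reset_index(drop=True),
        library_size=pd.Series(lib, name="library_size").reindex(names),
        windows=windows.reset_index(drop=True),
    )


def rpkm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """RPKM = count / ((window length / 1e3) * (library size / 1e6)).

    For 100-bp windows this is count * 1e7 / library_size.
    """
    zero = cm.library_size[cm.library_size <= 0]
    if len(zero):
        raise InputError(
            f"zero library size for sample(s): {', '.join(zero.index)}"
        )
    lengths = (cm.windows["end"] - cm.windows["start"]).to_numpy()
    scale = np.outer(
        1.0 / (lengths / 1e3),
        1.0 / (cm.library_size.to_numpy() / 1e6),
    )
    return pd.DataFrame(
        cm.counts.to_numpy() * scale,
        index=cm.counts.index,
        columns=cm.counts.columns,
    )


def filter_windows(cm: CountMatrix, min_total: int) -> CountMatrix:
    """Retain windows whose total count across samples is >= min_total."""
    if min_total < 0:
        raise InputError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    return CountMatrix(
        counts=cm.counts.loc[keep],
        samples=cm.samples,
        library_size=cm.library_size,
        windows=cm.windows[keep.to_numpy()].reset_index(drop=True),
    )
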