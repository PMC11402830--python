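"""Multi-species alignment analysis: conservation counts and logo matrices.

Works on a pre-built amino-acid multiple alignment (aligned FASTA, one
reference sequence, e.g. the human protein). Column conservation is
reported against the total number of aligned sequences ("conserved in 78
out of 80"), while logo frequencies are taken over non-gap characters
only — a deliberate asymmetry, documented here because both conventions
are standard in different corners of the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
STOP_CHAR = "*"
_ALPHABET = set(AA20) | set(GAP_CHARS) | {STOP_CHAR, "X"}

MAX_IC_BITS = math.log2(20)


@dataclass
class MultipleAlignment:
    """Named, equal-length gapped sequences with a designated reference."""

    ids: list[str]
    sequences: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise ValueError(
                    f"ragged alignment: sequence {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"sequence {sid!r} contains invalid characters {sorted(bad)}")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference(self) -> str:
        return self.sequences[self.ids.index(self.reference_id)]

    def column(self, col: int) -> str:
        """Characters of one 0-based column across all sequences."""
        return "".join(seq[col] for seq in self.sequences)


def read_alignment(path: str | Path, reference_id: str | None = None) -> MultipleAlignment:
    """Read an aligned FASTA; the reference defaults to the first record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return MultipleAlignment(ids, seqs, reference_id or ids[0])


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


@dataclass
class ExclusionReport:
    excluded: pd.DataFrame  # id, reason


def filter_sequences(
    aln: MultipleAlignment,
    max_missing_run: int = 30,
    *,
    min_internal_stops: int = 2,
    reject_internal_stops: bool = True,
) -> tuple[MultipleAlignment, ExclusionReport]:
    """Drop low-quality sequences, reporting the reason for each exclusion.

    A sequence is excluded when it contains ``min_internal_stops`` or more
    internal stop characters (default 2, i.e. "multiple stop codons"), or a
    run of gap/X characters longer than ``max_missing_run`` (a missing
    region). Trailing stops are not counted as internal.
    """
    keep_ids, keep_seqs, dropped = [], [], []
    for sid, seq in zip(aln.ids, aln.sequences):
        reason = None
        core = seq.rstrip(STOP_CHAR + "".join(GAP_CHARS))
        n_stops = core.count(STOP_CHAR)
        if reject_internal_stops and n_stops >= min_internal_stops:
            reason = f"multiple stop codons ({n_stops} internal stops)"
        else:
            run = best = 0
            for ch in seq:
                run = run + 1 if (ch in GAP_CHARS or ch == "X") else 0
                best = max(best, run)
            if best > max_missing_run:
                reason = f"missing region (gap/X run of {best} > {max_missing_run})"
        if reason is None:
            keep_ids.append(sid)
            keep_seqs.append(seq)
        else:
            dropped.append({"id": sid, "reason": reason})
    if not keep_ids:
        raise ValueError("all sequences excluded by filtering")
    report = ExclusionReport(pd.DataFrame(dropped, columns=["id", "reason"]))
    ref = aln.reference_id if aln.reference_id in keep_ids else keep_ids[0]
    return MultipleAlignment(keep_ids, keep_seqs, ref), report


def map_reference_position(aln: MultipleAlignment, ref_pos: int) -> int:
    """Alignment column (1-based) holding the ref_pos-th reference residue."""
    if ref_pos < 1:
        raise ValueError("reference positions are 1-based")
    seen = 0
    for col, ch in enumerate(aln.reference, start=1):
        if ch not in GAP_CHARS:
            seen += 1
            if seen == ref_pos:
                return col
    raise ValueError(
        f"reference position {ref_pos} beyond ungapped length {seen}"
    )


def conservation_count(
    aln: MultipleAlignment, column: int, residue: str
) -> tuple[int, int]:
    """(#sequences matching ``residue`` at 1-based ``column``, total sequences)."""
    if not (1 <= column <= aln.n_columns):
        raise ValueError(f"column {column} outside 1..{aln.n_columns}")
    chars = aln.column(column - 1)
    return chars.count(residue.upper()), len(aln)


def conservation_at(aln: MultipleAlignment, ref_pos: int, residue: str) -> tuple[int, int]:
    """Conservation count at the column of a reference position."""
    return conservation_count(aln, map_reference_position(aln, ref_pos), residue)


def logo_matrix(
    aln: MultipleAlignment,
    first_col: int,
    last_col: int,
    *,
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Per-column residue frequencies and information content (bits).

    Frequencies are over non-gap characters; IC(c) = log2(20) − H(c) with H
    the Shannon entropy of the column in bits, optionally reduced by the
    small-sample correction e(n) = 19/(2·ln2·n). Letter heights for a
    sequence logo are frequency × IC. All-gap columns get IC 0 and are
    flagged. Columns are 1-based and the range is inclusive.
    """
    if not (1 <= first_col <= last_col <= aln.n_columns):
        raise ValueError(f"invalid column range {first_col}..{last_col}")
    rows = []
    for col in range(first_col, last_col + 1):
        chars = [c for c in aln.column(col - 1) if c not in GAP_CHARS]
        rec: dict[str, object] = {"column": col}
        if not chars:
            for aa in AA20:
                rec[aa] = 0.0
            rec.update(information_bits=0.0, n_nongap=0, all_gap=True)
            rows.append(rec)
            continue
        n = len(chars)
        freqs = {aa: chars.count(aa) / n for aa in AA20}
        H = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        ic = MAX_IC_BITS - H
        if small_sample_correction:
            ic -= 19.0 / (2.0 * math.log(2) * n)
        rec.update(freqs)
        rec.update(information_bits=max(ic, 0.0), n_nongap=n, all_gap=False)
        rows.append(rec)
    return pd.DataFrame(rows)


def column_reference_map(aln: MultipleAlignment) -> pd.DataFrame:
    """Table mapping alignment columns to reference positions (NaN at gaps)."""
    ref = aln.reference
    pos = 0
    rows = []
    for col, ch in enumerate(ref, start=1):
        if ch in GAP_CHARS:
            rows.append({"column": col, "ref_pos": np.nan, "ref_aa": ""})
        else:
            pos += 1
            rows.append({"column": col, "ref_pos": pos, "ref_aa": ch})
    return pd.DataFrame(rows)
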