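"""Exact-match amplicon counting for barcoded Reel-seq libraries.

Reads have the layout ``barcode + fwd_primer + 31-nt variable region +
rev_primer``.  A read is assigned to a (SNP, allele) of one sequenced
library iff its barcode matches a library label exactly and the variable
region — located by exact match of both constant primers — equals a library
31-mer exactly.  Everything else is discarded with a reason tally
(bad barcode / primer not found / variable-region mismatch), mirroring the
perfect-sequence-match philosophy of the screen.

The :class:`CountMatrix` is a pandas DataFrame with a (snp_id, allele) row
index and a (cycle, condition, replicate) column index, one column per
sequenced library, plus per-label read-accounting metadata.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import LibraryDefinition

__all__ = [
    "LibraryLabel",
    "CountMatrix",
    "CountingError",
    "DISCARD_REASONS",
    "load_barcode_map",
    "write_barcode_map",
    "count_reads",
    "match_rate",
    "qc_complete",
]

CONDITIONS = ("control", "sample")
DEFAULT_CYCLES = (1, 4, 7, 10)
COLUMN_NAMES = ["cycle", "condition", "replicate"]
DISCARD_REASONS = ("bad_barcode", "primer_not_found", "variable_region_mismatch")

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class CountingError(ValueError):
    """Invalid counting input or undefined rate."""


class LibraryLabel(NamedTuple):
    """Identity of one sequenced library (one gel lane snapshot)."""

    cycle: int
    condition: str
    replicate: int
    barcode: str | None = None

    @property
    def key(self) -> tuple[int, str, int]:
        return (self.cycle, self.condition, self.replicate)


@dataclass
class CountMatrix:
    """Integer (or, in deterministic simulations, real-valued) read counts
    per (snp_id, allele) row and (cycle, condition, replicate) column."""

    df: pd.DataFrame
    #: per-label accounting: total_reads, matched_reads and discard tallies
    label_stats: pd.DataFrame | None = None
    #: reads whose barcode matched no label (not attributable to any column)
    n_bad_barcode: int = 0

    def __post_init__(self) -> None:
        if self.df.index.nlevels != 2:
            raise CountingError("row index must be (snp_id, allele)")
        if self.df.columns.nlevels != 3:
            raise CountingError("columns must be (cycle, condition, replicate)")
        self.df.index = self.df.index.set_names(["snp_id", "allele"])
        self.df.columns = self.df.columns.set_names(COLUMN_NAMES)
        if (self.df.values < 0).any():
            raise CountingError("negative counts")

    @property
    def labels(self) -> list[tuple[int, str, int]]:
        return list(self.df.columns)

    @property
    def cycles(self) -> list[int]:
        return sorted(self.df.columns.get_level_values("cycle").unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df.columns.get_level_values("replicate").unique())

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df.index.get_level_values("snp_id").unique())

    def counts(self, cycle: int, condition: str) -> pd.DataFrame:
        """Sub-matrix of all replicates for one (cycle, condition)."""
        return self.df.xs((cycle, condition), axis=1, level=("cycle", "condition"))

    def to_long(self, path: str | Path) -> None:
        """Write the matrix in long TSV form:
        snp_id, allele, cycle, condition, replicate, count."""
        long = self.df.stack(COLUMN_NAMES, future_stack=True).rename("count")
        long = long.reset_index()
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, path: str | Path) -> "CountMatrix":
        long = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "allele": str})
        missing = {"snp_id", "allele", *COLUMN_NAMES, "count"} - set(long.columns)
        if missing:
            raise CountingError(f"{path}: missing columns {sorted(missing)}")
        wide = long.pivot_table(
            index=["snp_id", "allele"],
            columns=COLUMN_NAMES,
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        # preserve first-appearance row order of the long file
        order = long[["snp_id", "allele"]].drop_duplicates()
        wide = wide.reindex(pd.MultiIndex.from_frame(order))
        if (long["count"] == long["count"].round()).all():
            wide = wide.astype(np.int64)
        return cls(df=wide)

    def equals_counts(self, other: "CountMatrix") -> bool:
        a = self.df.sort_index(axis=0).sort_index(axis=1)
        b = other.df.sort_index(axis=0).sort_index(axis=1)
        return a.shape == b.shape and bool(
            (a.index == b.index).all()
            and (a.columns == b.columns).all()
            and np.array_equal(a.values, b.values)
        )


def write_barcode_map(labels: Sequence[LibraryLabel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("barcode\tcycle\tcondition\treplicate\n")
        for lab in labels:
            fh.write(f"{lab.barcode}\t{lab.cycle}\t{lab.condition}\t{lab.replicate}\n")


def load_barcode_map(path: str | Path) -> list[LibraryLabel]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "condition": str})
    labels = [
        LibraryLabel(int(r.cycle), str(r.condition), int(r.replicate), str(r.barcode))
        for r in df.itertuples()
    ]
    _validate_labels(labels)
    return labels


def _validate_labels(labels: Sequence[LibraryLabel]) -> None:
    if not labels:
        raise CountingError("empty barcode map")
    keys = [lab.key for lab in labels]
    if len(set(keys)) != len(keys):
        raise CountingError("duplicate (cycle, condition, replicate) in barcode map")
    barcodes = [lab.barcode or "" for lab in labels]
    if len(set(barcodes)) != len(barcodes):
        raise CountingError("duplicate barcodes")
    for a in barcodes:
        for b in barcodes:
            if a != b and b.startswith(a):
                raise CountingError(
                    f"barcode {a!r} is a prefix of {b!r}; barcodes must be prefix-free"
                )


def count_reads(
    fastq_paths: str | Path | Iterable[str | Path],
    barcode_map: Sequence[LibraryLabel] | str | Path,
    lib: LibraryDefinition,
    accept_revcomp: bool = True,
) -> CountMatrix:
    """Demultiplex and count perfect-match reads into a CountMatrix.

    Deterministic for a fixed input order.  Reads failing any exact-match
    step are tallied per discard reason; bad-barcode reads cannot be
    attributed to a library and are tallied globally.
    """
    if isinstance(barcode_map, (str, Path)):
        barcode_map = load_barcode_map(barcode_map)
    else:
        _validate_labels(barcode_map)
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]

    bc_lengths = sorted({len(lab.barcode or "") for lab in barcode_map})
    bc_to_label = {lab.barcode: lab.key for lab in barcode_map}
    region_map = lib.variable_regions()
    fwd, rev = lib.fwd_primer, lib.rev_primer
    nf, nr = len(fwd), len(rev)
    vlen = 31

    rows = pd.MultiIndex.from_tuples(lib.sequence_index(), names=["snp_id", "allele"])
    cols = pd.MultiIndex.from_tuples([lab.key for lab in barcode_map], names=COLUMN_NAMES)
    row_pos = {ra: i for i, ra in enumerate(rows)}
    col_pos = {lab.key: j for j, lab in enumerate(barcode_map)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)

    stats = {
        key: {"total_reads": 0, "matched_reads": 0, "primer_not_found": 0,
              "variable_region_mismatch": 0}
        for key in col_pos
    }
    n_bad_barcode = 0

    def _extract_region(body: str) -> str | None:
        """Variable region located by exact match of both primers, else None."""
        if len(body) >= nf + vlen + nr and body.startswith(fwd) and body[
            nf + vlen : nf + vlen + nr
        ] == rev:
            return body[nf : nf + vlen]
        return None

    for path in fastq_paths:
        path = Path(path)
        if not path.exists():
            raise CountingError(f"unreadable FASTQ: {path}")
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                key = None
                body = None
                for blen in bc_lengths:
                    lab = bc_to_label.get(seq[:blen])
                    if lab is not None:
                        key = lab
                        body = seq[blen:]
                        break
                if key is None:
                    n_bad_barcode += 1
                    continue
                st = stats[key]
                st["total_reads"] += 1
                region = _extract_region(body)
                if region is None and accept_revcomp:
                    region = _extract_region(_revcomp(body))
                if region is None:
                    st["primer_not_found"] += 1
                    continue
                hit = region_map.get(region)
                if hit is None:
                    st["variable_region_mismatch"] += 1
                    continue
                counts[row_pos[hit], col_pos[key]] += 1
                st["matched_reads"] += 1

    df = pd.DataFrame(counts, index=rows, columns=cols)
    label_stats = pd.DataFrame.from_dict(stats, orient="index")
    label_stats.index = pd.MultiIndex.from_tuples(label_stats.index, names=COLUMN_NAMES)
    return CountMatrix(df=df, label_stats=label_stats, n_bad_barcode=n_bad_barcode)


def match_rate(cm: CountMatrix) -> tuple[float, pd.Series]:
    """Perfect-match fraction overall and per library label.

    The overall denominator includes reads that failed demultiplexing.
    """
    if cm.label_stats is None:
        raise CountingError("CountMatrix carries no read-accounting metadata")
    totals = cm.label_stats["total_reads"]
    matched = cm.label_stats["matched_reads"]
    grand_total = int(totals.sum()) + cm.n_bad_barcode
    if grand_total == 0:
        raise CountingError("match rate undefined: zero total reads")
    per_label = matched / totals.replace(0, np.nan)
    return float(matched.sum()) / grand_total, per_label


def qc_complete(
    cm: CountMatrix,
    alleles_of_interest: dict[str, Sequence[str]] | None = None,
    min_count: int = 1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Completeness QC: retain a SNP iff every examined allele has count
    ≥ ``min_count`` in every sequenced library.

    Returns the retained CountMatrix and a table of dropped SNPs with the
    first failing (allele, cycle, condition, replicate).
    """
    df = cm.df
    dropped_rows = []
    retained_ids = []
    for snp_id, sub in df.groupby(level="snp_id", sort=False):
        alleles = list(sub.index.get_level_values("allele"))
        if alleles_of_interest is not None:
            examined = [a for a in alleles if a in set(alleles_of_interest.get(snp_id, alleles))]
        else:
            examined = alleles
        block = sub.loc[[(snp_id, a) for a in examined]]
        bad = block.values < min_count
        if bad.any():
            i, j = np.argwhere(bad)[0]
            cyc, cond, rep = block.columns[j]
            dropped_rows.append(
                {
                    "snp_id": snp_id,
                    "allele": examined[i],
                    "cycle": cyc,
                    "condition": cond,
                    "replicate": rep,
                }
            )
        else:
            retained_ids.append(snp_id)
    dropped = pd.DataFrame(
        dropped_rows, columns=["snp_id", "allele", "cycle", "condition", "replicate"]
    )
    keep_mask = df.index.get_level_values("snp_id").isin(retained_ids)
    retained = CountMatrix(
        df=df.loc[keep_mask].copy(),
        label_stats=cm.label_stats,
        n_bad_barcode=cm.n_bad_barcode,
    )
    return retained, dropped
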