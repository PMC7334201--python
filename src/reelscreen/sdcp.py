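"""SDCP-MS peptide-spectrum-count triage.

SNP-specific DNA competition pulldown (SDCP) runs several 31-bp fSNP baits
in parallel, each in duplicate, so every bait doubles as the others'
negative control.  Proteins are triaged from the peptide-spectrum-count
table in two fixed steps:

1. **Nonspecific filter** — drop proteins with counts in *every* replicate
   column of *every* bait (ubiquitous binders: beads, ends, ssDNA).
2. **Reproducibility filter** — within each bait, evidence counts only if
   both replicates are positive; proteins with no reproducible bait are
   dropped.

What survives is called a bait-specific binder, annotated with the set of
baits it reproducibly bound and a specificity class (one bait / two baits /
multi-bait).  Presence means count ≥ ``min_count`` (default 1; spectrum
counts are integers and the procedure defines no higher threshold).

A packaged example table (:func:`load_fgfr2_example`) carries the spectrum
counts of the 19 binders recovered with the three FGFR2-locus fSNP baits
rs7895676, rs2981578 and rs2981584.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PeptideCountTable",
    "ProteinBindingCall",
    "SdcpError",
    "flag_nonspecific",
    "reproducible_baits",
    "call_bindings",
    "load_fgfr2_example",
]

STATUSES = ("nonspecific", "irreproducible", "retained")


class SdcpError(ValueError):
    """Invalid peptide-count table."""


@dataclass
class PeptideCountTable:
    """Protein × (bait, replicate) spectrum counts; absent = 0."""

    df: pd.DataFrame  # index: protein; columns: MultiIndex (bait, replicate)

    def __post_init__(self) -> None:
        cols = self.df.columns
        if cols.nlevels != 2:
            raise SdcpError("columns must be a (bait, replicate) MultiIndex")
        self.df.columns = cols.set_names(["bait", "replicate"])
        reps = self.df.columns.to_frame(index=False).groupby("bait")["replicate"].count()
        if (reps != 2).any():
            bad = reps[reps != 2].index.tolist()
            raise SdcpError(f"each bait needs exactly 2 replicate columns: {bad}")
        if len(reps) < 2:
            raise SdcpError("need at least 2 baits (each is the others' control)")
        if (self.df.to_numpy() < 0).any():
            raise SdcpError("negative spectrum counts")
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()].tolist()
            raise SdcpError(f"duplicate protein rows: {dup}")

    @property
    def baits(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values("bait")))

    @property
    def proteins(self) -> list[str]:
        return list(self.df.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeptideCountTable":
        """Read ``protein, <bait>_1, <bait>_2, ...`` TSV/CSV."""
        sep = "," if str(path).endswith(".csv") else "\t"
        raw = pd.read_csv(path, sep=sep).set_index("protein")
        tuples = []
        for col in raw.columns:
            bait, _, rep = col.rpartition("_")
            if not bait or not rep.isdigit():
                raise SdcpError(f"{path}: column {col!r} is not <bait>_<replicate>")
            tuples.append((bait, int(rep)))
        raw.columns = pd.MultiIndex.from_tuples(tuples)
        return cls(df=raw.fillna(0).astype(int))

    def to_tsv(self, path: str | Path) -> None:
        flat = self.df.copy()
        flat.columns = [f"{b}_{r}" for b, r in flat.columns]
        flat.rename_axis("protein").to_csv(path, sep="\t")


@dataclass
class ProteinBindingCall:
    protein: str
    status: str
    bound_baits: tuple[str, ...]
    specificity: str | None  # one_bait / two_baits / multi_bait when retained


def flag_nonspecific(table: PeptideCountTable, min_count: int = 1) -> set[str]:
    """Proteins with counts in every replicate column of every bait."""
    mask = (table.df >= min_count).all(axis=1)
    return set(table.df.index[mask])


def reproducible_baits(
    table: PeptideCountTable, protein: str, min_count: int = 1
) -> set[str]:
    """Baits at which both replicates of ``protein`` are positive."""
    row = table.df.loc[protein]
    present = (row >= min_count).groupby(level="bait").all()
    return set(present.index[present])


def _specificity(n_baits: int) -> str:
    return {1: "one_bait", 2: "two_baits"}.get(n_baits, "multi_bait")


def call_bindings(
    table: PeptideCountTable, min_count: int = 1
) -> tuple[list[ProteinBindingCall], dict]:
    """Run the two filters in order and call bait-specific binders.

    Returns per-protein calls plus a summary: totals removed by each
    filter, retained count, and retained counts per specificity class.
    """
    nonspecific = flag_nonspecific(table, min_count)
    calls: list[ProteinBindingCall] = []
    for protein in table.proteins:
        if protein in nonspecific:
            calls.append(ProteinBindingCall(protein, "nonspecific", (), None))
            continue
        baits = reproducible_baits(table, protein, min_count)
        if not baits:
            calls.append(ProteinBindingCall(protein, "irreproducible", (), None))
        else:
            ordered = tuple(b for b in table.baits if b in baits)
            calls.append(
                ProteinBindingCall(protein, "retained", ordered, _specificity(len(ordered)))
            )
    retained = [c for c in calls if c.status == "retained"]
    summary = {
        "n_proteins": len(calls),
        "n_nonspecific": sum(c.status == "nonspecific" for c in calls),
        "n_irreproducible": sum(c.status == "irreproducible" for c in calls),
        "n_retained": len(retained),
        "specificity": {
            cls: sum(c.specificity == cls for c in retained)
            for cls in ("one_bait", "two_baits", "multi_bait")
        },
    }
    return calls, summary


def calls_to_frame(calls: list[ProteinBindingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [c.protein for c in calls],
            "status": [c.status for c in calls],
            "bound_baits": [",".join(c.bound_baits) for c in calls],
            "specificity": [c.specificity or "" for c in calls],
        }
    )


def load_fgfr2_example() -> PeptideCountTable:
    """Packaged spectrum-count table: 19 binders × 3 FGFR2-locus fSNP baits
    (duplicate pulldowns per bait)."""
    path = resources.files("reelscreen.data").joinpath("fgfr2_sdcp_counts.tsv")
    with resources.as_file(path) as p:
        return PeptideCountTable.from_tsv(p)
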