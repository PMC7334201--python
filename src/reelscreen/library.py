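"""SNP library model for the Reel-seq screen.

A Reel-seq library is a pool of synthetic double-stranded oligos, one per
SNP allele.  Each oligo carries a 31-bp variable region — the SNP at the
centre (position 16, 1-based) flanked by 15 nt of genomic context on each
side — placed between two constant PCR primers used for amplification and
regeneration between selection cycles.  With the default 22-nt primers the
full unselected construct is 75 bp, the size of the unshifted band cut from
the native gel each cycle.

Flanks are stored per SNP rather than looked up from a reference genome:
the physical library is synthesized from fixed 31-bp windows, so the model
never needs external sequence data.  Coordinates are reported 1-based;
internally slices are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SnpRecord",
    "LibraryDefinition",
    "LibraryError",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
    "SNP_POSITION",
    "VARIABLE_REGION_LENGTH",
    "FLANK_LENGTH",
    "build_variable_region",
    "assemble_construct",
    "enumerate_sequences",
    "load_library",
    "write_library",
    "write_constructs_fasta",
]

DNA_ALPHABET = frozenset("ACGT")

#: 1-based position of the SNP inside the variable region.
SNP_POSITION = 16
FLANK_LENGTH = 15
VARIABLE_REGION_LENGTH = 2 * FLANK_LENGTH + 1  # 31

# Constant amplification primers.  The published screen names its primers but
# not their sequences; these 22-nt defaults reproduce the 75-bp unshifted
# construct and are configuration, not biology.
DEFAULT_FWD_PRIMER = "ACACGACGCTCTTCCGATCTGG"
DEFAULT_REV_PRIMER = "CCAGACGTGTGCTCTTCCGATC"

TSV_COLUMNS = ["snp_id", "locus", "alleles", "risk_allele", "flank5", "flank3"]


class LibraryError(ValueError):
    """Invalid library definition, record, or allele."""


def _check_dna(seq: str, what: str) -> None:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise LibraryError(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class SnpRecord:
    """One library SNP: 2–4 single-nucleotide alleles with fixed 15-nt flanks."""

    snp_id: str
    locus: str
    alleles: tuple[str, ...]
    risk_allele: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if not 2 <= len(self.alleles) <= 4:
            raise LibraryError(
                f"{self.snp_id}: expected 2-4 alleles, got {len(self.alleles)}"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise LibraryError(f"{self.snp_id}: duplicate alleles {self.alleles}")
        for a in self.alleles:
            if len(a) != 1 or a not in DNA_ALPHABET:
                raise LibraryError(f"{self.snp_id}: invalid allele {a!r}")
        if self.risk_allele not in self.alleles:
            raise LibraryError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} not among "
                f"alleles {self.alleles}"
            )
        if len(self.flank5) != FLANK_LENGTH or len(self.flank3) != FLANK_LENGTH:
            raise LibraryError(
                f"{self.snp_id}: flanks must be {FLANK_LENGTH} nt "
                f"(got {len(self.flank5)}/{len(self.flank3)})"
            )
        _check_dna(self.flank5, f"{self.snp_id} flank5")
        _check_dna(self.flank3, f"{self.snp_id} flank3")

    def variable_region(self, allele: str) -> str:
        """31-nt variable region with `allele` at position 16 (1-based)."""
        if allele not in self.alleles:
            raise LibraryError(
                f"{self.snp_id}: allele {allele!r} not in {self.alleles}"
            )
        return self.flank5 + allele + self.flank3

    @property
    def nonrisk_alleles(self) -> tuple[str, ...]:
        return tuple(a for a in self.alleles if a != self.risk_allele)


@dataclass
class LibraryDefinition:
    """An ordered Reel-seq library with its constant primers.

    Variable regions must be unique across all alleles of all SNPs so that
    perfect-match read counting is unambiguous.
    """

    records: list[SnpRecord] = field(default_factory=list)
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        self.records = list(self.records)
        _check_dna(self.fwd_primer, "fwd_primer")
        _check_dna(self.rev_primer, "rev_primer")
        seen_ids: set[str] = set()
        seen_regions: dict[str, tuple[str, str]] = {}
        for rec in self.records:
            if rec.snp_id in seen_ids:
                raise LibraryError(f"duplicate snp_id {rec.snp_id!r}")
            seen_ids.add(rec.snp_id)
            for allele in rec.alleles:
                region = rec.variable_region(allele)
                if region in seen_regions:
                    other = seen_regions[region]
                    raise LibraryError(
                        f"variable-region collision: {rec.snp_id}/{allele} "
                        f"equals {other[0]}/{other[1]}"
                    )
                seen_regions[region] = (rec.snp_id, allele)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryDefinition):
            return NotImplemented
        return (
            self.records == other.records
            and self.fwd_primer == other.fwd_primer
            and self.rev_primer == other.rev_primer
        )

    @property
    def n_sequences(self) -> int:
        return enumerate_sequences(self)

    def record(self, snp_id: str) -> SnpRecord:
        for rec in self.records:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)

    def sequence_index(self) -> list[tuple[str, str]]:
        """All (snp_id, allele) pairs in library order."""
        return [(rec.snp_id, a) for rec in self.records for a in rec.alleles]

    def variable_regions(self) -> dict[str, tuple[str, str]]:
        """Map 31-mer -> (snp_id, allele); unique by the class invariant."""
        return {
            rec.variable_region(a): (rec.snp_id, a)
            for rec in self.records
            for a in rec.alleles
        }


def build_variable_region(snp: SnpRecord, allele: str) -> str:
    """Assemble the 31-nt SNP-centred variable region for one allele."""
    return snp.variable_region(allele)


def assemble_construct(lib: LibraryDefinition, snp: SnpRecord, allele: str) -> str:
    """Full oligo: fwd primer + 31-nt variable region + rev primer."""
    return lib.fwd_primer + snp.variable_region(allele) + lib.rev_primer


def enumerate_sequences(lib: LibraryDefinition | Iterable[SnpRecord]) -> int:
    """Number of allele-specific sequences in the library (Σ per-SNP alleles)."""
    records = lib.records if isinstance(lib, LibraryDefinition) else lib
    return sum(len(rec.alleles) for rec in records)


def write_library(lib: LibraryDefinition, path: str | Path) -> None:
    """Write the library as TSV: header, then one row per SNP.

    Alleles are comma-joined in column order.  Primers are stored in a
    leading comment line so the format round-trips completely.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#fwd_primer={lib.fwd_primer}\trev_primer={lib.rev_primer}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in lib.records:
            fh.write(
                "\t".join(
                    [
                        rec.snp_id,
                        rec.locus,
                        ",".join(rec.alleles),
                        rec.risk_allele,
                        rec.flank5,
                        rec.flank3,
                    ]
                )
                + "\n"
            )


def load_library(path: str | Path) -> LibraryDefinition:
    """Load a library TSV, validating all invariants; errors name the row."""
    path = Path(path)
    fwd, rev = DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER
    records: list[SnpRecord] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    body_start = 0
    if lines and lines[0].startswith("#"):
        for part in lines[0].lstrip("#").split("\t"):
            key, _, val = part.partition("=")
            if key == "fwd_primer":
                fwd = val
            elif key == "rev_primer":
                rev = val
        body_start = 1
    if body_start >= len(lines):
        raise LibraryError(f"{path}: empty library file")
    header = lines[body_start].split("\t")
    if header != TSV_COLUMNS:
        raise LibraryError(
            f"{path}: bad header {header!r}, expected {TSV_COLUMNS!r}"
        )
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(TSV_COLUMNS):
            raise LibraryError(
                f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        snp_id, locus, alleles_s, risk, flank5, flank3 = fields
        try:
            rec = SnpRecord(
                snp_id=snp_id,
                locus=locus,
                alleles=tuple(alleles_s.split(",")),
                risk_allele=risk,
                flank5=flank5,
                flank3=flank3,
            )
        except LibraryError as exc:
            raise LibraryError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    try:
        return LibraryDefinition(records=records, fwd_primer=fwd, rev_primer=rev)
    except LibraryError as exc:
        raise LibraryError(f"{path}: {exc}") from exc


def write_constructs_fasta(lib: LibraryDefinition, path: str | Path) -> None:
    """FASTA of every allele construct, headers `>{snp_id}|{allele}|{risk|nonrisk}`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in lib.records:
            for allele in rec.alleles:
                tag = "risk" if allele == rec.risk_allele else "nonrisk"
                fh.write(f">{rec.snp_id}|{allele}|{tag}\n")
                fh.write(assemble_construct(lib, rec, allele) + "\n")
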