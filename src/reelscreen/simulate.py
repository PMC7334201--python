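"""Forward simulator of the cyclic gel-shift (Reel-seq) selection.

The screen incubates a pooled oligo library with nuclear extract (sample)
or buffer (control), separates protein-bound from free DNA on a native gel,
recovers the *unshifted* band, and regenerates it by PCR for the next
cycle; snapshots of selected cycles are sequenced.  A molecule of sequence
*i* is shifted out of the unshifted band with probability ``p_shift_i``, so
one cycle multiplies its relative frequency by ``(1 - p_shift_i)`` followed
by renormalization (PCR regeneration restores total material — only
relative frequencies are observable at fixed sequencing depth).

A functional SNP (fSNP) is one whose alleles differ in ``p_shift`` under
nuclear extract: its within-SNP allele ratio then changes geometrically
with cycle number, which is what the downstream statistics detect.
Buffer-only loss is allele-independent (nonspecific shifting is even and
random), so the control allele ratio is constant and the noise-free
normalized ratio (sample ÷ control) after cycle ``c`` has the closed form
``[(1 - p_r) / (1 - p_n)]**c`` — the simulator's deterministic mode
reproduces this exactly and serves as the analysis oracle.

Each of the 5 control + 5 sample replicate libraries evolves as an
independent lineage from the uniform initial pool, as in the physical
screen where ten parallel reactions are carried through all ten cycles.
All randomness flows from a single seeded generator with a fixed draw
order: model assignment, then lineages by condition (control first), then
replicate, then cycle; a multinomial sequencing draw at each snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .counting import (
    COLUMN_NAMES,
    CountMatrix,
    LibraryLabel,
)
from .library import LibraryDefinition, SnpRecord, assemble_construct

__all__ = [
    "AlleleShiftModel",
    "SimulationConfig",
    "SimulationTruth",
    "DegenerateLibraryError",
    "apply_cycle",
    "expected_normalized_ratio",
    "sequence_library",
    "simulate_screen",
    "emit_fastq",
    "random_library",
    "make_barcodes",
    "default_labels",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class DegenerateLibraryError(RuntimeError):
    """Selection wiped out the whole library (no surviving material)."""


@dataclass
class AlleleShiftModel:
    """Per-sequence shift probabilities under nuclear extract, plus the
    allele-independent buffer-only loss applied to every sequence."""

    #: indexed by (snp_id, allele); values in [0, 1)
    p_sample: pd.Series
    p_control: float = 0.0

    def __post_init__(self) -> None:
        vals = self.p_sample.to_numpy(dtype=float)
        if ((vals < 0) | (vals >= 1)).any():
            raise ValueError("p_shift_sample must lie in [0, 1)")
        if not 0 <= self.p_control < 1:
            raise ValueError("p_shift_control must lie in [0, 1)")

    def aligned(self, lib: LibraryDefinition) -> np.ndarray:
        idx = pd.MultiIndex.from_tuples(lib.sequence_index())
        return self.p_sample.reindex(idx).to_numpy(dtype=float)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults mirror the published screen design: 5 buffer controls + 5
    nuclear-extract samples carried through 10 cycles with cycles 1, 4, 7
    and 10 sequenced.  ``delta_p`` is the allele difference in shift
    probability given to functional SNPs on top of ``baseline_p``; the
    direction (risk allele shifted more or less) is assigned at random per
    fSNP.  ``depth`` is reads per sequenced library.
    """

    n_snps: int = 500
    fraction_functional: float = 0.1
    delta_p: float = 0.3
    baseline_p: float = 0.1
    control_p: float = 0.0
    replicates: int = 5
    n_cycles: int = 10
    sequenced_cycles: tuple[int, ...] = (1, 4, 7, 10)
    depth: int = 50_000
    pcr_noise_sd: float = 0.0
    mode: str = "stochastic"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sequenced_cycles = tuple(int(c) for c in self.sequenced_cycles)
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not set(self.sequenced_cycles) <= set(range(1, self.n_cycles + 1)):
            raise ValueError("sequenced_cycles must lie within 1..n_cycles")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.fraction_functional <= 1:
            raise ValueError("fraction_functional must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sequenced_cycles"] = list(self.sequenced_cycles)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated screen, for recovery benchmarking."""

    model: AlleleShiftModel
    #: per SNP: is_functional, p_risk, p_nonrisk, expected_slope_sign
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def functional_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_functional"], "snp_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_cycle(
    freqs: np.ndarray,
    p_shift: np.ndarray | float,
    pcr_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One selection cycle: survival by (1 − p_shift), then renormalization.

    With ``pcr_noise_sd > 0`` each surviving term is multiplied by an
    i.i.d. lognormal amplification factor before renormalization.
    """
    freqs = np.asarray(freqs, dtype=float)
    survived = freqs * (1.0 - np.asarray(p_shift, dtype=float))
    if pcr_noise_sd > 0:
        if rng is None:
            raise ValueError("pcr_noise_sd > 0 requires an rng")
        survived = survived * rng.lognormal(0.0, pcr_noise_sd, size=survived.shape)
    total = survived.sum()
    if total <= 0:
        raise DegenerateLibraryError("no material survived the selection cycle")
    return survived / total


def expected_normalized_ratio(
    p_r: float | np.ndarray,
    p_n: float | np.ndarray,
    p_ctrl: float = 0.0,
    cycle: int | np.ndarray = 1,
) -> float | np.ndarray:
    """Noise-free normalized allele ratio after ``cycle`` selection cycles.

    sample(risk/non-risk) ÷ control(risk/non-risk) = [(1−p_r)/(1−p_n)]^c
    when the buffer-only loss ``p_ctrl`` is allele-independent (it then
    cancels from the control ratio).
    """
    p_r, p_n = np.asarray(p_r, dtype=float), np.asarray(p_n, dtype=float)
    out = ((1.0 - p_r) / (1.0 - p_n)) ** np.asarray(cycle)
    return out.item() if out.ndim == 0 else out


def sequence_library(
    freqs: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial sequencing snapshot: integer counts summing to ``depth``."""
    freqs = np.asarray(freqs, dtype=float)
    if depth <= 0:
        raise ValueError("depth must be positive")
    return rng.multinomial(depth, freqs / freqs.sum())


def _assign_shift_model(
    lib: LibraryDefinition, config: SimulationConfig, rng: np.random.Generator
) -> tuple[AlleleShiftModel, SimulationTruth]:
    """Draw which SNPs are functional and build per-sequence probabilities.

    Functional SNPs put ``baseline_p + delta_p`` on one allele of the
    (risk, first non-risk) pair — risk or non-risk with equal probability —
    and the baseline on all others; non-functional SNPs are flat."""
    n_func = int(round(config.fraction_functional * len(lib.records)))
    func_idx = set(
        rng.choice(len(lib.records), size=n_func, replace=False).tolist()
    )
    p: dict[tuple[str, str], float] = {}
    rows = []
    for i, rec in enumerate(lib.records):
        nonrisk = rec.nonrisk_alleles[0]
        for a in rec.alleles:
            p[(rec.snp_id, a)] = config.baseline_p
        if i in func_idx:
            hot = rec.risk_allele if rng.random() < 0.5 else nonrisk
            p[(rec.snp_id, hot)] = config.baseline_p + config.delta_p
        p_r = p[(rec.snp_id, rec.risk_allele)]
        p_n = p[(rec.snp_id, nonrisk)]
        rows.append(
            {
                "snp_id": rec.snp_id,
                "is_functional": i in func_idx,
                "p_risk": p_r,
                "p_nonrisk": p_n,
                # slope of the normalized ratio [(1-p_r)/(1-p_n)]^c
                "expected_slope_sign": int(np.sign(p_n - p_r)),
            }
        )
    series = pd.Series(p)
    series.index = pd.MultiIndex.from_tuples(series.index, names=["snp_id", "allele"])
    model = AlleleShiftModel(p_sample=series, p_control=config.control_p)
    return model, SimulationTruth(model=model, table=pd.DataFrame(rows))


def simulate_screen(
    lib: LibraryDefinition,
    config: SimulationConfig,
    model: AlleleShiftModel | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Run the full screen: independent replicate lineages per condition,
    sequencing snapshots after the selection step of each named cycle.

    In deterministic mode the snapshot is the exact (infinite-depth)
    expectation ``frequency × depth`` as real numbers; in stochastic mode
    it is a multinomial draw of ``depth`` reads.
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        model, truth = _assign_shift_model(lib, config, rng)
    else:
        # external model: truth reconstructed from it
        rows = []
        for rec in lib.records:
            nonrisk = rec.nonrisk_alleles[0]
            p_r = float(model.p_sample[(rec.snp_id, rec.risk_allele)])
            p_n = float(model.p_sample[(rec.snp_id, nonrisk)])
            per_snp = [float(model.p_sample[(rec.snp_id, a)]) for a in rec.alleles]
            rows.append(
                {
                    "snp_id": rec.snp_id,
                    "is_functional": len(set(per_snp)) > 1,
                    "p_risk": p_r,
                    "p_nonrisk": p_n,
                    "expected_slope_sign": int(np.sign(p_n - p_r)),
                }
            )
        truth = SimulationTruth(model=model, table=pd.DataFrame(rows))

    n_seq = lib.n_sequences
    p_sample = model.aligned(lib)
    p_by_condition = {
        "control": np.full(n_seq, model.p_control),
        "sample": p_sample,
    }
    rows_idx = pd.MultiIndex.from_tuples(lib.sequence_index(), names=["snp_id", "allele"])
    cols = pd.MultiIndex.from_tuples(
        [
            (c, cond, rep)
            for cond in ("control", "sample")
            for rep in range(1, config.replicates + 1)
            for c in config.sequenced_cycles
        ],
        names=COLUMN_NAMES,
    )
    dtype = float if config.mode == "deterministic" else np.int64
    out = np.zeros((n_seq, len(cols)), dtype=dtype)
    col_pos = {key: j for j, key in enumerate(cols)}

    for cond in ("control", "sample"):
        p_shift = p_by_condition[cond]
        for rep in range(1, config.replicates + 1):
            freqs = np.full(n_seq, 1.0 / n_seq)
            for cyc in range(1, config.n_cycles + 1):
                freqs = apply_cycle(freqs, p_shift, config.pcr_noise_sd, rng)
                if cyc in config.sequenced_cycles:
                    j = col_pos[(cyc, cond, rep)]
                    if config.mode == "deterministic":
                        out[:, j] = freqs * config.depth
                    else:
                        out[:, j] = sequence_library(freqs, config.depth, rng)

    cm = CountMatrix(df=pd.DataFrame(out, index=rows_idx, columns=cols))
    # column order: cycle-major for readability
    cm.df = cm.df.sort_index(
        axis=1, level=["cycle", "condition", "replicate"], sort_remaining=False
    )
    return cm, truth


def make_barcodes(n: int, length: int = 8) -> list[str]:
    """Deterministic list of ``n`` distinct fixed-length barcodes.

    Fixed length makes the set trivially prefix-free."""
    if n > 4**length:
        raise ValueError("not enough distinct barcodes at this length")
    out = []
    for i in range(n):
        digits = []
        x = i
        for _ in range(length):
            digits.append("ACGT"[x % 4])
            x //= 4
        out.append("".join(reversed(digits)))
    return out


def default_labels(
    cycles: Sequence[int] = (1, 4, 7, 10),
    replicates: int = 5,
    barcode_length: int = 8,
) -> list[LibraryLabel]:
    """Labels for the standard 40-library layout, with barcodes attached."""
    keys = [
        (c, cond, rep)
        for c in cycles
        for cond in ("control", "sample")
        for rep in range(1, replicates + 1)
    ]
    barcodes = make_barcodes(len(keys), barcode_length)
    return [LibraryLabel(c, cond, rep, bc) for (c, cond, rep), bc in zip(keys, barcodes)]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def emit_fastq(
    cm: CountMatrix,
    lib: LibraryDefinition,
    labels: Sequence[LibraryLabel],
    path: str | Path,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> int:
    """Write the CountMatrix as barcoded FASTQ reads; returns reads written.

    Each read is ``barcode + fwd_primer + variable region + rev_primer``
    with uniform quality; the read multiset per library matches the counts
    exactly.  ``error_rate`` injects i.i.d. per-base substitutions.
    """
    label_by_key = {lab.key: lab for lab in labels}
    for key in cm.labels:
        if key not in label_by_key or label_by_key[key].barcode is None:
            raise ValueError(f"no barcode for library column {key}")
    rng = np.random.default_rng(seed)

    constructs = np.vstack(
        [
            _encode(assemble_construct(lib, rec, a))
            for rec in lib.records
            for a in rec.alleles
        ]
    )
    row_index = pd.MultiIndex.from_tuples(cm.df.index, names=["snp_id", "allele"])
    lib_index = pd.MultiIndex.from_tuples(lib.sequence_index())
    # cm rows may be a subset/permutation of the library
    row_to_construct = lib_index.get_indexer(row_index)
    if (row_to_construct < 0).any():
        raise ValueError("CountMatrix contains rows not present in the library")

    path = Path(path)
    n_written = 0
    base_lut = _BASES
    code_of = np.full(256, -1, dtype=np.int8)
    for k, b in enumerate(b"ACGT"):
        code_of[b] = k

    with path.open("wb") as fh:
        for j, key in enumerate(cm.labels):
            counts = np.asarray(cm.df.iloc[:, j])
            if not np.allclose(counts, np.round(counts)):
                raise ValueError(
                    "emit_fastq requires integer counts (stochastic-mode matrix)"
                )
            counts = np.round(counts).astype(np.int64)
            total = int(counts.sum())
            if total == 0:
                continue
            barcode = _encode(label_by_key[key].barcode)
            reads = np.empty((total, len(barcode) + constructs.shape[1]), dtype=np.uint8)
            reads[:, : len(barcode)] = barcode
            reads[:, len(barcode):] = np.repeat(
                constructs[row_to_construct], counts, axis=0
            )
            if error_rate > 0:
                mask = rng.random(reads.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    codes = code_of[reads[mask]]
                    shift = rng.integers(1, 4, size=n_err)
                    reads[mask] = base_lut[(codes + shift) % 4]
            qual = b"I" * reads.shape[1]
            seqs = reads.view(f"S{reads.shape[1]}").ravel()
            cyc, cond, rep = key
            chunk = b"".join(
                b"@%s_c%d_r%d_%d\n%s\n+\n%s\n"
                % (cond.encode(), cyc, rep, n_written + i, s, qual)
                for i, s in enumerate(seqs)
            )
            fh.write(chunk)
            n_written += total
    return n_written


def random_library(
    n_snps: int,
    seed: int | np.random.Generator = 0,
    n_triallelic: int = 0,
    n_quadallelic: int = 0,
    locus: str = "simulated",
) -> LibraryDefinition:
    """Generate a synthetic library with unique random flanks.

    SNP ids are ``rs<k>``-style synthetic labels; flank uniqueness
    guarantees unambiguous perfect-match counting."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_triallelic + n_quadallelic > n_snps:
        raise ValueError("more multi-allelic SNPs than SNPs")
    records = []
    seen_flanks: set[str] = set()
    for i in range(n_snps):
        while True:
            flanks = "".join(rng.choice(list("ACGT"), size=30))
            if flanks not in seen_flanks:
                seen_flanks.add(flanks)
                break
        if i < n_quadallelic:
            k = 4
        elif i < n_quadallelic + n_triallelic:
            k = 3
        else:
            k = 2
        alleles = tuple(rng.permutation(list("ACGT"))[:k].tolist())
        records.append(
            SnpRecord(
                snp_id=f"rs{1000000 + i}",
                locus=locus,
                alleles=alleles,
                risk_allele=alleles[0],
                flank5=flanks[:15],
                flank3=flanks[15:],
            )
        )
    return LibraryDefinition(records=records)
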