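"""UMI- and barcode-tagged long-read simulation from repeat elements.

Reads are emitted in rolling windows anchored at each element's 3' end
(the end an oligo-dT-primed cDNA is captured from), stepping 5'-ward at a
fixed stride.  Each (element, window) pair yields one molecule with a fresh
unique UMI; the molecule is emitted `coverage` times with independent
errors, emulating PCR duplicates.  Nanopore-like error is applied by
drawing a per-read alignment identity from a scaled Beta distribution and
corrupting the sequence with a substitution/insertion/deletion mix.

Truth (source element, true interval, molecule id, true UMI) is encoded in
the read name so downstream evaluation never needs side channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import RepeatAnnotation, reverse_complement

__all__ = [
    "ErrorModelParams",
    "AdapterLayout",
    "SimulationConfig",
    "SimulatedMolecule",
    "SimulatedRead",
    "rolling_windows",
    "make_umi",
    "draw_identity",
    "corrupt",
    "assemble_read",
    "simulate_molecules",
    "emit_reads",
    "simulate_arm",
    "parse_read_name",
    "write_fastq",
    "read_fastq",
]

_BASES = "ACGT"
NAME_DELIM = "|"

# Synthetic adapter oligos (fixed arbitrary sequences; real oligo sets are
# supplied through AdapterLayout / preprocess.AdapterConfig).
DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTACAT"
DEFAULT_DT_ADAPTER = "CTACACGACGCTCTTCCGATCTGTGGTATC"
DEFAULT_BARCODE = "ACGTTGCAGGTCAATG"


@dataclass(frozen=True)
class ErrorModelParams:
    """Moments of the per-read identity distribution plus the error mix.

    Identities are drawn as max_identity * Beta(a, b) with (a, b) chosen by
    method of moments so draws have the stated mean and standard deviation
    and never exceed max_identity.  Defaults follow a nanopore-like profile
    with mean 92%, max 96%, sd 2.5%.
    """

    mean_identity: float = 0.92
    max_identity: float = 0.96
    sd_identity: float = 0.025
    error_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # sub, ins, del
    perfect_quality: int = 40

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_identity < self.max_identity <= 1.0):
            raise ValueError("require 0 < mean_identity < max_identity <= 1")
        if self.sd_identity <= 0:
            raise ValueError("sd_identity must be > 0")
        mix = self.error_mix
        if len(mix) != 3 or any(m < 0 for m in mix) or abs(sum(mix) - 1) > 1e-9:
            raise ValueError("error_mix must be 3 non-negative proportions summing to 1")
        self.beta_shapes()  # validate moment feasibility eagerly

    def beta_shapes(self) -> tuple[float, float]:
        """Method-of-moments Beta shapes for identity/max_identity."""
        m = self.mean_identity / self.max_identity
        v = (self.sd_identity / self.max_identity) ** 2
        if v >= m * (1 - m):
            raise ValueError("sd_identity too large for a Beta with this mean/max")
        common = m * (1 - m) / v - 1.0
        return m * common, (1 - m) * common


@dataclass(frozen=True)
class AdapterLayout:
    """Read structure: tso + cdna + umi + barcode + dt_adapter (5'->3')."""

    tso: str = DEFAULT_TSO
    dt_adapter: str = DEFAULT_DT_ADAPTER


@dataclass(frozen=True)
class SimulationConfig:
    window_length: int = 2000
    stride: int = 500
    coverage: int = 1
    identity_mode: str = "perfect"  # or "ont"
    umi_length: int = 22
    umi_pattern: str = "RYN"
    barcode: str = DEFAULT_BARCODE
    adapter_layout: AdapterLayout = field(default_factory=AdapterLayout)
    error_model: ErrorModelParams = field(default_factory=ErrorModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.stride < 1 or self.coverage < 1:
            raise ValueError("window_length, stride and coverage must be >= 1")
        if self.identity_mode not in ("perfect", "ont"):
            raise ValueError("identity_mode must be 'perfect' or 'ont'")


@dataclass(frozen=True)
class SimulatedMolecule:
    molecule_id: str
    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    window_index: int
    true_umi: str
    barcode: str
    cdna: str


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    drawn_identity: float

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError("quality and sequence lengths differ")


def rolling_windows(
    element: RepeatAnnotation, window_length: int, stride: int
) -> list[tuple[str, int, int, str]]:
    """Windows fully inside the element, anchored at its biological 3' end.

    For a + strand element the 3' end is the interval end; the first window
    abuts it and successive windows shift 5'-ward (leftward) by `stride`.
    Minus-strand elements mirror this.  Windows longer than the element
    yield an empty list; no truncated windows are emitted.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    out = []
    if window_length > element.length:
        return out
    if element.strand == "+":
        start = element.end - window_length
        while start >= element.start:
            out.append((element.chrom, start, start + window_length, "+"))
            start -= stride
    else:
        start = element.start
        while start + window_length <= element.end:
            out.append((element.chrom, start, start + window_length, "-"))
            start += stride
    return out


def make_umi(length: int, pattern: str, rng: np.random.Generator) -> str:
    """Random UMI; RYN cycles purine/pyrimidine/any, NNN is uniform."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if pattern == "NNN":
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    if pattern == "RYN":
        out = []
        for i in range(length):
            cyc = i % 3
            if cyc == 0:
                out.append("AG"[rng.integers(0, 2)])
            elif cyc == 1:
                out.append("CT"[rng.integers(0, 2)])
            else:
                out.append(_BASES[rng.integers(0, 4)])
        return "".join(out)
    raise ValueError(f"unknown UMI pattern {pattern!r}")


def draw_identity(
    params: ErrorModelParams, rng: np.random.Generator, size: int | None = None
):
    """Per-read identity: max_identity * Beta(a, b), method-of-moments."""
    a, b = params.beta_shapes()
    return params.max_identity * rng.beta(a, b, size=size)


def corrupt(
    sequence: str,
    target_identity: float,
    error_mix: tuple[float, float, float],
    rng: np.random.Generator,
) -> str:
    """Corrupt a sequence so its alignment identity to the input is ~target.

    With per-base event rate eps split into (sub, ins, del) proportions
    (ms, mi, md), the expected alignment identity (matches over alignment
    columns) is (1 - eps(ms+md)) / (1 + eps*mi); eps is solved so this
    equals target_identity.  Events are placed uniformly and independently.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return sequence
    ms, mi, md = error_mix
    eps = (1.0 - target_identity) / (ms + md + target_identity * mi)
    n = len(sequence)
    u = rng.random(n)
    p_sub, p_ins, p_del = eps * ms, eps * mi, eps * md
    out: list[str] = []
    for i in range(n):
        r = u[i]
        base = sequence[i]
        if r < p_del:
            continue
        if r < p_del + p_sub:
            j = _BASES.index(base) if base in _BASES else rng.integers(0, 4)
            out.append(_BASES[(j + rng.integers(1, 4)) % 4])
        else:
            out.append(base)
        if r >= 1.0 - p_ins:  # independent tail of the same uniform draw
            out.append(_BASES[rng.integers(0, 4)])
    return "".join(out)


def _phred_char(q: int) -> str:
    return chr(min(q, 93) + 33)


def _identity_to_q(identity: float) -> int:
    err = max(1.0 - identity, 1e-9)
    return max(2, int(round(-10.0 * np.log10(err))))


def _check_fields(fields: list[str]) -> None:
    for f in fields:
        if NAME_DELIM in f:
            raise ValueError(f"reserved delimiter {NAME_DELIM!r} in field {f!r}")


def assemble_read(
    molecule: SimulatedMolecule,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_index: int = 0,
) -> SimulatedRead:
    """Adapterise a molecule and apply the arm's identity mode.

    Layout: tso + cdna + umi + barcode + dt_adapter.  In perfect mode the
    read is the template with a constant Q40 quality string; in ONT mode a
    drawn identity corrupts the whole adapterised sequence.
    """
    if not molecule.cdna:
        raise ValueError("cdna must be non-empty")
    lay = config.adapter_layout
    template = (
        lay.tso + molecule.cdna + molecule.true_umi + molecule.barcode + lay.dt_adapter
    )
    fields = [
        f"{molecule.molecule_id}r{read_index}",
        molecule.molecule_id,
        molecule.element_id,
        molecule.chrom,
        str(molecule.start),
        str(molecule.end),
        molecule.strand,
        molecule.true_umi,
    ]
    _check_fields(fields)
    read_id = NAME_DELIM.join(fields)
    if config.identity_mode == "perfect":
        q = _phred_char(config.error_model.perfect_quality)
        return SimulatedRead(read_id, template, q * len(template), 1.0)
    identity = float(draw_identity(config.error_model, rng))
    seq = corrupt(template, identity, config.error_model.error_mix, rng)
    qual = _phred_char(_identity_to_q(identity)) * len(seq)
    return SimulatedRead(read_id, seq, qual, identity)


def parse_read_name(read_id: str) -> dict:
    """Invert the truth encoding of assemble_read."""
    f = read_id.split(NAME_DELIM)
    if len(f) != 8:
        raise ValueError(f"not a simulated read name: {read_id!r}")
    return {
        "read_id": read_id,
        "molecule_id": f[1],
        "element_id": f[2],
        "chrom": f[3],
        "start": int(f[4]),
        "end": int(f[5]),
        "strand": f[6],
        "true_umi": f[7],
    }


def simulate_molecules(
    annotations: list[RepeatAnnotation],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimulatedMolecule]:
    """One molecule per (element, rolling window), each with a unique UMI."""
    ids = [a.element_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("element_id collision in annotations")
    molecules = []
    seen_umis: set[str] = set()
    for ann in annotations:
        windows = rolling_windows(ann, config.window_length, config.stride)
        for w_idx, (chrom, start, end, strand) in enumerate(windows):
            umi = make_umi(config.umi_length, config.umi_pattern, rng)
            while umi in seen_umis:
                umi = make_umi(config.umi_length, config.umi_pattern, rng)
            seen_umis.add(umi)
            cdna = genome[chrom][start:end]
            if strand == "-":
                cdna = reverse_complement(cdna)
            molecules.append(
                SimulatedMolecule(
                    molecule_id=f"{ann.element_id}.w{w_idx}",
                    element_id=ann.element_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    window_index=w_idx,
                    true_umi=umi,
                    barcode=config.barcode,
                    cdna=cdna,
                )
            )
    return molecules


def emit_reads(
    molecules: list[SimulatedMolecule],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Emit each molecule `coverage` times with independent errors."""
    reads = []
    for mol in molecules:
        for k in range(config.coverage):
            reads.append(assemble_read(mol, config, rng, read_index=k))
    return reads


def simulate_arm(
    annotations: list[RepeatAnnotation],
    genome: dict[str, str],
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Full simulation of one experiment arm.

    Returns the reads and a molecule truth table (one row per molecule).
    Total reads = coverage x sum over elements of window count.
    """
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(annotations, genome, config, rng)
    reads = emit_reads(molecules, config, rng)
    truth = pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "element_id": [m.element_id for m in molecules],
            "chrom": [m.chrom for m in molecules],
            "start": [m.start for m in molecules],
            "end": [m.end for m in molecules],
            "strand": [m.strand for m in molecules],
            "umi": [m.true_umi for m in molecules],
        }
    )
    return reads, truth


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[SimulatedRead]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            out.append(SimulatedRead(header[1:].rstrip("\n"), seq, qual, float("nan")))
    return out
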