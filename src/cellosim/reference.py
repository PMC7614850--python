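"""Synthetic repeat-family references.

Desk-scale stand-ins for RepeatMasker-annotated repeat families: a single
ancestral sequence is mutated into divergent copies which are planted at
non-overlapping positions in random background sequence.  Divergence is
parameterised in milliDivergence (substitutions per 1000 aligned sites),
the unit RepeatMasker reports, so truth annotations are directly comparable
with real repeat tracks.  Also provides the Jukes-Cantor conversion from
milliDivergence to element age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RepeatFamilySpec",
    "RepeatAnnotation",
    "PlacementError",
    "generate_ancestral",
    "diverge_copy",
    "plant_copies",
    "jc_age",
    "write_fasta",
    "write_bed",
    "write_divergence_table",
    "read_fasta",
    "read_bed",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Upper bound of the Jukes-Cantor domain in milliDivergence units.
JC_MAX_MILLI_DIV = 750.0

#: Default neutral substitution rate (substitutions/site/year), a standard
#: mammalian value; configurable in :func:`jc_age`.
DEFAULT_SUBST_RATE = 2.2e-9


class PlacementError(RuntimeError):
    """Raised when repeat copies cannot be placed without overlap."""


@dataclass(frozen=True)
class RepeatFamilySpec:
    """Parameters of a synthetic repeat family.

    divergence_range is in milliDivergence (substitutions per 1000 sites);
    each planted copy draws its divergence uniformly from this range.
    """

    ancestral_length: int
    copy_number: int
    genome_length: int
    divergence_range: tuple[float, float] = (0.0, 100.0)
    indel_rate: float = 0.0
    gc_content: float = 0.5
    seed: int = 0
    subfamily: str = "SYNF1"
    #: optional explicit per-copy divergences, cycled over the copies;
    #: overrides uniform draws from divergence_range
    divergence_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.ancestral_length < 1:
            raise ValueError("ancestral_length must be >= 1")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi <= JC_MAX_MILLI_DIV):
            raise ValueError(
                f"divergence_range must lie in [0, {JC_MAX_MILLI_DIV}]"
            )
        if self.divergence_grid is not None and not all(
            0.0 <= d <= JC_MAX_MILLI_DIV for d in self.divergence_grid
        ):
            raise ValueError("divergence_grid values must lie in [0, 750]")
        if self.copy_number * self.ancestral_length >= self.genome_length:
            raise ValueError("total planted length must be < genome_length")


@dataclass(frozen=True)
class RepeatAnnotation:
    """A planted (or real) repeat element with 0-based half-open coordinates."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    milli_div: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0.0 <= self.milli_div <= JC_MAX_MILLI_DIV):
            raise ValueError("milli_div out of [0, 750]")

    @property
    def length(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_ancestral(length: int, gc: float = 0.5, seed=None) -> str:
    """Random i.i.d. nucleotide sequence with the given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=length, p=p)
    return np.array([b"A", b"C", b"G", b"T"])[idx].tobytes().decode()


def diverge_copy(
    ancestral: str,
    milli_div: float,
    indel_rate: float = 0.0,
    seed=None,
) -> tuple[str, float]:
    """Mutate a copy of the ancestral sequence.

    Each site is substituted independently with probability milli_div/1000
    (to a uniformly chosen different base).  Insertions and deletions each
    occur at indel_rate/2 per site.  Returns the mutated sequence and the
    realized milliDivergence: substitutions per 1000 surviving (aligned)
    ancestral sites.
    """
    if not (0.0 <= milli_div <= JC_MAX_MILLI_DIV):
        raise ValueError(f"milli_div must be in [0, {JC_MAX_MILLI_DIV}]")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(ancestral)
    arr = np.frombuffer(ancestral.encode(), dtype="S1").copy()

    sub_mask = rng.random(n) < milli_div / 1000.0
    n_sub = int(sub_mask.sum())
    if n_sub:
        # substitute to a uniformly chosen *different* base
        cur = arr[sub_mask]
        offs = rng.integers(1, 4, size=n_sub)
        codes = np.searchsorted(BASES, cur)
        arr[sub_mask] = BASES[(codes + offs) % 4]

    if indel_rate == 0.0:
        realized = 1000.0 * n_sub / n
        return arr.tobytes().decode(), realized

    del_mask = rng.random(n) < indel_rate / 2.0
    ins_mask = rng.random(n) < indel_rate / 2.0
    out: list[str] = []
    n_kept = 0
    n_sub_kept = 0
    for i in range(n):
        if not del_mask[i]:
            out.append(chr(arr[i][0]))
            n_kept += 1
            if sub_mask[i]:
                n_sub_kept += 1
        if ins_mask[i]:
            out.append(chr(BASES[rng.integers(0, 4)][0]))
    if n_kept == 0:
        return "", 0.0
    realized = 1000.0 * n_sub_kept / n_kept
    return "".join(out), realized


def plant_copies(
    spec: RepeatFamilySpec, chrom: str = "chr1", max_tries: int = 1000
) -> tuple[dict[str, str], list[RepeatAnnotation]]:
    """Plant divergent copies of one ancestral sequence in random background.

    Returns ({chrom: sequence}, annotations).  Positions are uniform subject
    to non-overlap; strands uniform; minus-strand copies are inserted
    reverse-complemented.  The annotation records the copy's true interval
    and realized milliDivergence.
    """
    rng = np.random.default_rng(spec.seed)
    ancestral = generate_ancestral(spec.ancestral_length, spec.gc_content, rng)

    copies: list[tuple[str, float]] = []
    lo, hi = spec.divergence_range
    for i in range(spec.copy_number):
        if spec.divergence_grid is not None:
            mdiv = float(spec.divergence_grid[i % len(spec.divergence_grid)])
        else:
            mdiv = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        copies.append(diverge_copy(ancestral, mdiv, spec.indel_rate, rng))

    background = generate_ancestral(spec.genome_length, spec.gc_content, rng)
    genome = np.frombuffer(background.encode(), dtype="S1").copy()

    placed: list[tuple[int, int]] = []
    annotations: list[RepeatAnnotation] = []
    for i, (seq, realized) in enumerate(copies):
        L = len(seq)
        if L > spec.genome_length:
            raise PlacementError("copy longer than genome")
        for attempt in range(max_tries):
            start = int(rng.integers(0, spec.genome_length - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise PlacementError(
                f"could not place copy {i} without overlap after {max_tries} tries"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = seq if strand == "+" else reverse_complement(seq)
        genome[start:end] = np.frombuffer(inserted.encode(), dtype="S1")
        placed.append((start, end))
        annotations.append(
            RepeatAnnotation(
                element_id=f"{spec.subfamily}_{i:03d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                subfamily=spec.subfamily,
                milli_div=realized,
            )
        )
    annotations.sort(key=lambda a: a.start)
    return {chrom: genome.tobytes().decode()}, annotations


def jc_age(milli_div: float, subst_rate: float = DEFAULT_SUBST_RATE) -> float:
    """Jukes-Cantor age (million years) from milliDivergence.

    d = -(3/4) ln(1 - 4p/3) with p = milli_div/1000; age = d / (2 r) / 1e6,
    with divergence accruing on both lineages (element vs consensus).
    """
    if subst_rate <= 0:
        raise ValueError("subst_rate must be > 0")
    p = milli_div / 1000.0
    if p < 0:
        raise ValueError("milli_div must be >= 0")
    if p >= 0.75:
        raise ValueError("Jukes-Cantor distance undefined for p >= 0.75")
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    return d / (2.0 * subst_rate) / 1e6


# ---------------------------------------------------------------------------
# I/O: FASTA via Biopython, BED6 + divergence TSV as plain text


def write_fasta(genome: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_bed(annotations: list[RepeatAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.element_id}\t"
                f"{round(a.milli_div)}\t{a.strand}\n"
            )


def read_bed(path, subfamily: str = "NA") -> list[RepeatAnnotation]:
    annotations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            annotations.append(
                RepeatAnnotation(
                    element_id=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                    subfamily=subfamily,
                    milli_div=float(f[4]) if len(f) > 4 else 0.0,
                )
            )
    return annotations


def write_divergence_table(annotations: list[RepeatAnnotation], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "element_id": [a.element_id for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "strand": [a.strand for a in annotations],
            "subfamily": [a.subfamily for a in annotations],
            "milli_div": [a.milli_div for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)
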