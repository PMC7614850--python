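"""Read mapping, CIGAR identity, read classification and specificity.

An internal oracle mapper (optimal semi-global edit-distance placement via
edlib, exhaustive over every chromosome and strand) maps desk-scale
instances; production-scale alignments from an external long-read aligner
can be imported as PAF with extended (=/X) CIGARs instead.

Each simulated read is classified against its encoded truth:
mapped    - primary alignment overlaps the true interval by >= 1 bp;
mismapped - aligned, but with no overlap of the true interval;
unmapped  - no alignment;
unresolved- the read/consensus came from a UMI group mixing molecules.

Per element, a specificity score summarises locus-level mappability:
mapped reads of the element over mapped plus foreign reads mis-aligned
into the element's interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .reference import RepeatAnnotation, reverse_complement

__all__ = [
    "AlignmentRecord",
    "ReadClassification",
    "ElementSummary",
    "oracle_map",
    "read_identity",
    "classify",
    "element_summary",
    "specificity",
    "read_paf",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDMSHN])")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    cigar: str
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.target_end <= self.target_start:
            raise ValueError("target_end must be > target_start")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    klass: str  # mapped | mismapped | unmapped | unresolved
    overlap_bases: int
    true_element_id: str
    aligned_element_id: str | None


@dataclass
class ElementSummary:
    element_id: str
    n_mapped: int = 0
    n_mismapped_own: int = 0
    n_unmapped: int = 0
    n_unresolved: int = 0
    n_mismapped_in: int = 0

    @property
    def n_total(self) -> int:
        return self.n_mapped + self.n_mismapped_own + self.n_unmapped + self.n_unresolved

    @property
    def fraction_mapped(self) -> float:
        return self.n_mapped / self.n_total if self.n_total else float("nan")

    @property
    def specificity(self) -> float | None:
        return specificity(self)


def read_identity(cigar: str) -> float:
    """matches / (matches + mismatches + insertions + deletions).

    Requires an extended CIGAR distinguishing = and X; plain M is rejected
    because it hides mismatches.
    """
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        pos = m.end()
        if op == "M":
            raise ValueError("CIGAR with undifferentiated M; need =/X ops")
        if op in counts:
            counts[op] += n
    if pos != len(cigar):
        raise ValueError(f"unparseable CIGAR: {cigar!r}")
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("empty CIGAR")
    return counts["="] / denom


def _candidate_loci(locations: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse optimal end positions that describe one locus.

    edlib reports every optimal (start, end); ends within one span length
    of each other are treated as the same locus, keeping the first.
    """
    loci: list[tuple[int, int]] = []
    for start, end in sorted(locations):
        if loci and start <= loci[-1][1]:
            continue
        loci.append((start, end))
    return loci


def oracle_map(
    query: str,
    reference: dict[str, str],
    rng=None,
    min_identity: float = 0.7,
    read_id: str = "",
) -> AlignmentRecord | None:
    """Optimal semi-global placement of the query in the reference.

    Both strands of every chromosome are searched exhaustively (bit-vector
    edit distance, optimal within edlib's infix mode, i.e. equivalent to
    full DP).  Among equal-best loci one is chosen uniformly at random
    under the run seed, mirroring aligner behaviour on exact repeats.
    Returns None (unmapped) when best identity < min_identity.
    """
    rng = np.random.default_rng(rng)
    best_dist = None
    candidates: list[tuple[str, str, int, int]] = []  # chrom, strand, start, end
    queries = {"+": query, "-": reverse_complement(query)}
    for chrom, ref in reference.items():
        for strand, q in queries.items():
            res = edlib.align(q, ref, mode="HW", task="locations")
            d = res["editDistance"]
            if d == -1:
                continue
            if best_dist is None or d < best_dist:
                best_dist = d
                candidates = []
            if d == best_dist:
                for s, e in _candidate_loci(res["locations"]):
                    candidates.append((chrom, strand, s, e + 1))
    if best_dist is None or not candidates:
        return None
    chrom, strand, start, end = candidates[int(rng.integers(0, len(candidates)))]
    q = queries[strand]
    cigar = edlib.align(q, reference[chrom][start:end], mode="NW", task="path")["cigar"]
    if read_identity(cigar) < min_identity:
        return None
    return AlignmentRecord(read_id, chrom, start, end, strand, cigar)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify(
    alignments: dict[str, AlignmentRecord | None],
    truth: dict[str, dict],
    unresolved_ids: set[str] = frozenset(),
    annotations: list[RepeatAnnotation] | None = None,
) -> list[ReadClassification]:
    """Per-read verdicts against simulation truth.

    truth maps read id -> {element_id, chrom, start, end}.  Reads in
    unresolved_ids (members/outputs of impure UMI groups) are unresolved
    regardless of their alignment.
    """
    out = []
    for read_id, aln in alignments.items():
        if read_id not in truth:
            raise ValueError(f"no truth for read {read_id!r}")
        t = truth[read_id]
        aligned_el = None
        if aln is not None and annotations is not None:
            aligned_el = _containing_element(aln, annotations)
        if read_id in unresolved_ids:
            out.append(
                ReadClassification(read_id, "unresolved", 0, t["element_id"], aligned_el)
            )
            continue
        if aln is None:
            out.append(
                ReadClassification(read_id, "unmapped", 0, t["element_id"], None)
            )
            continue
        ov = 0
        if aln.target_chrom == t["chrom"]:
            ov = _overlap(aln.target_start, aln.target_end, t["start"], t["end"])
        klass = "mapped" if ov >= 1 else "mismapped"
        out.append(ReadClassification(read_id, klass, ov, t["element_id"], aligned_el))
    return out


def _containing_element(
    aln: AlignmentRecord, annotations: list[RepeatAnnotation]
) -> str | None:
    best, best_ov = None, 0
    for a in annotations:
        if a.chrom != aln.target_chrom:
            continue
        ov = _overlap(aln.target_start, aln.target_end, a.start, a.end)
        if ov > best_ov:
            best, best_ov = a.element_id, ov
    return best


def element_summary(
    classifications: list[ReadClassification],
    alignments: dict[str, AlignmentRecord | None],
    annotations: list[RepeatAnnotation],
) -> dict[str, ElementSummary]:
    """Per-element tallies; elements with no simulated reads are absent.

    n_mismapped_in counts *foreign* mismapped reads whose alignment
    interval overlaps the element by >= 1 bp.
    """
    summaries: dict[str, ElementSummary] = {}
    for c in classifications:
        s = summaries.setdefault(c.true_element_id, ElementSummary(c.true_element_id))
        if c.klass == "mapped":
            s.n_mapped += 1
        elif c.klass == "mismapped":
            s.n_mismapped_own += 1
        elif c.klass == "unmapped":
            s.n_unmapped += 1
        else:
            s.n_unresolved += 1
    by_id = {a.element_id: a for a in annotations}
    for c in classifications:
        if c.klass != "mismapped":
            continue
        aln = alignments[c.read_id]
        for a in annotations:
            if a.element_id == c.true_element_id or a.chrom != aln.target_chrom:
                continue
            if _overlap(aln.target_start, aln.target_end, a.start, a.end) >= 1:
                if a.element_id in summaries:
                    summaries[a.element_id].n_mismapped_in += 1
    return summaries


def specificity(summary: ElementSummary) -> float | None:
    """n_mapped / (n_mapped + n_mismapped_in); None when the denominator is 0."""
    denom = summary.n_mapped + summary.n_mismapped_in
    if denom == 0:
        return None
    return summary.n_mapped / denom


def read_paf(path) -> dict[str, AlignmentRecord]:
    """Import primary alignments from PAF with a cg:Z: extended CIGAR."""
    out: dict[str, AlignmentRecord] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            tags = dict(t.split(":", 2)[::2] for t in f[12:])
            if tags.get("tp", "P") != "P":
                continue
            cg = next((t.split(":", 2)[2] for t in f[12:] if t.startswith("cg:")), None)
            if cg is None:
                raise ValueError("PAF record without cg:Z: CIGAR tag")
            if "M" in cg:
                raise ValueError("PAF CIGAR uses M; rerun the aligner with =/X ops")
            rec = AlignmentRecord(
                read_id=f[0],
                target_chrom=f[5],
                target_start=int(f[7]),
                target_end=int(f[8]),
                strand=f[4],
                cigar=cg,
            )
            if f[0] not in out:
                out[f[0]] = rec
    return out
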