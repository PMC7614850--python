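"""Front-end read processing for UMI-tagged long reads.

Mirrors the front half of a consensus-calling pipeline for noisy long
reads: local alignment of the TSO and dT-side adapters against a window at
either read end, filtering for full-length (double-adapter) reads with
canonical re-orientation, screening for internal adapters (chimeras from
blunt ligation), barcode demultiplexing by Levenshtein distance, and
positional UMI extraction anchored on the called dT adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .readsim import (
    DEFAULT_BARCODE,
    DEFAULT_DT_ADAPTER,
    DEFAULT_TSO,
    SimulatedRead,
)
from .reference import reverse_complement

__all__ = [
    "AdapterConfig",
    "AdapterHit",
    "AnnotatedRead",
    "scan_read_ends",
    "filter_full_length",
    "internal_adapter_policy",
    "demultiplex",
    "extract_umi",
    "preprocess_reads",
]


@dataclass(frozen=True)
class AdapterConfig:
    tso_sequence: str = DEFAULT_TSO
    dt_adapter_sequence: str = DEFAULT_DT_ADAPTER
    end_window: int = 250
    #: fraction of the adapter's self-alignment score required to call a hit
    min_alignment_fraction: float = 0.6
    #: stricter score fraction for internal (mid-read) calls, where a long
    #: stretch of unrelated sequence gives chance local alignments
    internal_min_fraction: float = 0.75
    internal_split_threshold: float = 0.20
    barcode_whitelist: tuple[str, ...] = (DEFAULT_BARCODE,)
    barcode_distance_threshold: int = 3
    umi_length: int = 22
    barcode_length: int = len(DEFAULT_BARCODE)

    def __post_init__(self) -> None:
        if not (0.0 < self.min_alignment_fraction <= 1.0):
            raise ValueError("min_alignment_fraction must be in (0, 1]")
        longest = max(len(self.tso_sequence), len(self.dt_adapter_sequence))
        if self.end_window < longest:
            raise ValueError("end_window must cover the longest adapter")


@dataclass(frozen=True)
class AdapterHit:
    adapter: str  # "tso" or "dt"
    end: str  # "head", "tail" or "internal"
    orientation: str  # "+" (as given) or "-" (reverse complement matched)
    score: float
    start: int  # read coordinates, 0-based half-open
    stop: int


@dataclass
class AnnotatedRead:
    read_id: str
    sequence: str
    quality: str
    hits: list[AdapterHit] = field(default_factory=list)
    barcode_call: str | None = None
    umi: str | None = None
    cdna: str | None = None
    reason: str | None = None  # set when excluded


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


_ALIGNER = _aligner()


def _best_local(adapter: str, window: str) -> tuple[float, int, int]:
    """Best local alignment score and the *full-adapter* window span.

    Local alignment may clip the adapter's first/last bases; the span is
    extrapolated to where the complete adapter would sit, so positional
    extraction anchored on it does not drift with clipping.
    """
    if not window:
        return 0.0, 0, 0
    aln = _ALIGNER.align(window, adapter)
    best = aln[0]
    tstart = int(best.aligned[0][0][0])
    tstop = int(best.aligned[0][-1][1])
    qstart = int(best.aligned[1][0][0])
    qstop = int(best.aligned[1][-1][1])
    full_start = max(0, tstart - qstart)
    full_stop = min(len(window), tstop + (len(adapter) - qstop))
    return float(best.score), full_start, full_stop


def _scan_region(
    seq: str,
    offset: int,
    end_label: str,
    config: AdapterConfig,
    min_fraction: float | None = None,
) -> list[AdapterHit]:
    if min_fraction is None:
        min_fraction = config.min_alignment_fraction
    hits = []
    for name, adapter in (
        ("tso", config.tso_sequence),
        ("dt", config.dt_adapter_sequence),
    ):
        min_score = min_fraction * len(adapter)
        for orient, query in (("+", adapter), ("-", reverse_complement(adapter))):
            score, s, e = _best_local(query, seq)
            if score >= min_score:
                hits.append(AdapterHit(name, end_label, orient, score, offset + s, offset + e))
    return hits


def scan_read_ends(read, config: AdapterConfig) -> list[AdapterHit]:
    """Call adapters in a window at either end of the read (both orientations)."""
    seq = read.sequence
    if not seq:
        raise ValueError("read is empty")
    w = config.end_window
    hits = _scan_region(seq[:w], 0, "head", config)
    if len(seq) > w:
        hits += _scan_region(seq[-w:], len(seq) - w, "tail", config)
    return hits


def _best_hit(hits: list[AdapterHit], adapter: str, end: str) -> AdapterHit | None:
    cands = [h for h in hits if h.adapter == adapter and h.end == end]
    return max(cands, key=lambda h: h.score) if cands else None


def filter_full_length(
    reads: list, config: AdapterConfig
) -> tuple[list[AnnotatedRead], list[AnnotatedRead]]:
    """Keep reads with a TSO at one end and a dT adapter at the other.

    Kept reads are re-oriented canonically (TSO forward at the 5' head);
    discarded reads carry a reason code.  kept + discarded == input.
    """
    kept, discarded = [], []
    for read in reads:
        hits = scan_read_ends(read, config)
        fwd_tso = _best_hit(hits, "tso", "head")
        fwd_dt = _best_hit(hits, "dt", "tail")
        rev_tso = _best_hit(hits, "tso", "tail")
        rev_dt = _best_hit(hits, "dt", "head")

        fwd_ok = (
            fwd_tso is not None
            and fwd_dt is not None
            and fwd_tso.orientation == "+"
            and fwd_dt.orientation == "+"
        )
        rev_ok = (
            rev_tso is not None
            and rev_dt is not None
            and rev_tso.orientation == "-"
            and rev_dt.orientation == "-"
        )
        if fwd_ok and (not rev_ok or fwd_tso.score + fwd_dt.score >= rev_tso.score + rev_dt.score):
            kept.append(
                AnnotatedRead(read.read_id, read.sequence, read.quality, hits=hits)
            )
        elif rev_ok:
            seq = reverse_complement(read.sequence)
            ann = AnnotatedRead(read.read_id, seq, read.quality[::-1])
            ann.hits = scan_read_ends(ann, config)
            kept.append(ann)
        else:
            reason = "no_adapters" if not hits else "missing_adapter_pair"
            discarded.append(
                AnnotatedRead(
                    read.read_id, read.sequence, read.quality, hits=hits, reason=reason
                )
            )
    return kept, discarded


def _internal_hits(read, config: AdapterConfig) -> list[AdapterHit]:
    """Adapter alignments falling outside both end windows."""
    seq = read.sequence
    w = config.end_window
    if len(seq) <= 2 * w:
        return []
    hits = _scan_region(
        seq[w : len(seq) - w], w, "internal", config,
        min_fraction=config.internal_min_fraction,
    )
    return hits


def internal_adapter_policy(
    reads: list, config: AdapterConfig
) -> tuple[str, list, list]:
    """Split chimeric reads if internal adapters are common, else drop them.

    If the fraction of reads with an internal adapter call exceeds
    internal_split_threshold the decision is "split": each affected read is
    cut at the midpoint of its internal alignment (adapter bases removed
    from both halves).  Otherwise the decision is "filter" and affected
    reads are dropped.  Returns (decision, surviving reads, dropped reads).
    """
    flagged: dict[int, AdapterHit] = {}
    for i, read in enumerate(reads):
        ih = _internal_hits(read, config)
        if ih:
            flagged[i] = max(ih, key=lambda h: h.score)
    if not reads:
        return "filter", [], []
    frac = len(flagged) / len(reads)
    if frac > config.internal_split_threshold:
        out = []
        for i, read in enumerate(reads):
            if i not in flagged:
                out.append(read)
                continue
            hit = flagged[i]
            out.append(
                SimulatedRead(
                    read.read_id + "/1",
                    read.sequence[: hit.start],
                    read.quality[: hit.start],
                    getattr(read, "drawn_identity", float("nan")),
                )
            )
            out.append(
                SimulatedRead(
                    read.read_id + "/2",
                    read.sequence[hit.stop :],
                    read.quality[hit.stop :],
                    getattr(read, "drawn_identity", float("nan")),
                )
            )
        return "split", out, []
    dropped = [
        AnnotatedRead(
            reads[i].read_id, reads[i].sequence, reads[i].quality,
            reason="internal_adapter",
        )
        for i in flagged
    ]
    return "filter", [r for i, r in enumerate(reads) if i not in flagged], dropped


def demultiplex(
    reads: list[AnnotatedRead], config: AdapterConfig
) -> dict[str, str | None]:
    """Assign each read's barcode to the nearest whitelist entry.

    A read is assigned iff the minimal Levenshtein distance is <= the
    threshold and uniquely attained; ties and far barcodes are unassigned.
    """
    if not config.barcode_whitelist:
        raise ValueError("barcode whitelist is empty")
    calls: dict[str, str | None] = {}
    for read in reads:
        segment = _barcode_segment(read, config)
        if segment is None:
            calls[read.read_id] = None
            read.barcode_call = None
            continue
        # infix distance: the segment carries a little positional slack, so
        # the barcode is matched as a substring rather than end-to-end
        dists = [
            edlib.align(bc, segment, mode="HW", task="distance")["editDistance"]
            for bc in config.barcode_whitelist
        ]
        best = min(dists)
        if best <= config.barcode_distance_threshold and dists.count(best) == 1:
            call = config.barcode_whitelist[dists.index(best)]
        else:
            call = None
        calls[read.read_id] = call
        read.barcode_call = call
    return calls


def _layout_anchor(read: AnnotatedRead, config: AdapterConfig):
    """(tso_end, dt_start) on the canonically oriented read, or None."""
    hits = read.hits or scan_read_ends(read, config)
    tso = _best_hit(hits, "tso", "head")
    dt = _best_hit(hits, "dt", "tail")
    if tso is None or dt is None:
        return None
    return tso.stop, dt.start


def _barcode_segment(read: AnnotatedRead, config: AdapterConfig) -> str | None:
    anchor = _layout_anchor(read, config)
    if anchor is None:
        return None
    _, dt_start = anchor
    slack = 4  # absorbs indel drift between the dT call and the barcode
    s = max(0, dt_start - config.barcode_length - slack)
    return read.sequence[s:dt_start] if dt_start > s else None


def extract_umi(
    read: AnnotatedRead, config: AdapterConfig
) -> tuple[str, str] | None:
    """Positional UMI/cdna extraction anchored on the called adapters.

    Layout (canonical orientation): tso | cdna | umi | barcode | dt.
    Returns (umi, cdna) or None (read flagged) when the read is too short
    to contain the layout.
    """
    anchor = _layout_anchor(read, config)
    if anchor is None:
        read.reason = "missing_adapter_pair"
        return None
    tso_end, dt_start = anchor
    umi_start = dt_start - config.barcode_length - config.umi_length
    if umi_start < tso_end:
        read.reason = "too_short_for_layout"
        return None
    umi = read.sequence[umi_start : umi_start + config.umi_length]
    cdna = read.sequence[tso_end:umi_start]
    read.umi, read.cdna = umi, cdna
    return umi, cdna


def preprocess_reads(
    reads: list, config: AdapterConfig
) -> tuple[list[AnnotatedRead], list[AnnotatedRead]]:
    """Internal-adapter policy -> full-length filter -> demux -> UMI extraction.

    Returns (kept, excluded); every excluded read carries a reason code.
    """
    _, screened, internally_dropped = internal_adapter_policy(reads, config)
    kept, discarded = filter_full_length(screened, config)
    demultiplex(kept, config)
    out, excluded = [], internally_dropped + list(discarded)
    for read in kept:
        if read.barcode_call is None:
            read.reason = "unassigned_barcode"
            excluded.append(read)
            continue
        if extract_umi(read, config) is None:
            excluded.append(read)
            continue
        out.append(read)
    return out, excluded
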